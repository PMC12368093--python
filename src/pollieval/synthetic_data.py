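"""Synthetic time-lapse ground truth and simulated detector outputs.

The generator emulates the statistical structure of a field time-lapse
study of flower visitors, so the whole evaluation pipeline can be exercised
and calibrated without image downloads:

* ~200 recording sessions of about an hour at one frame per 1.6 s;
* visitors arrive sparsely (about 6 per session) and stay for a geometric
  number of frames calibrated to a median of 7 boxes per individual, with
  occasional occlusion gaps during which the identifier is retained;
* relative box areas are log-normal (median ~0.028, mean ~0.075 before
  truncation at the frame) — most visitors are small, a few fill the frame;
* a latent sharpness is coupled to box area (small = far from the fixed
  focal plane = blurry), targeting a Spearman correlation of ~0.79;
* class mix ~79% Hymenoptera / 11% Diptera / 10% other taxa.

The detector simulator emits per-box predictions with localisation
probability driven by area and sharpness (or injected per-group
sequence-level rates for parameter-recovery studies), label noise from a
row-stochastic confusion matrix with elevated Hymenoptera<->Diptera mass
(hoverfly mimicry), confidence drawn higher for correct labels, box jitter,
optional duplicate boxes, and Poisson background false positives.

All randomness flows from explicit seeds; no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    Box,
    DEFAULT_GROUPING,
    GROUPS,
    GroundTruthAnnotation,
    IndividualSequence,
    Prediction,
    TAXA,
    assemble_individuals,
    group_of,
)

__all__ = [
    "SynthConfig",
    "DetectorModel",
    "SyntheticDataset",
    "gen_ground_truth",
    "simulate_detector",
    "gen_blur_patches",
    "default_confusion",
    "geometric_p_for_median",
    "sharpness_noise_for_rho",
]

#: Fine taxa within the OtherT group, weighted by their observed shares of
#: OtherT individuals (ants dominate, then beetles, bugs, spiders).
_OTHERT_TAXA = ("Hymenoptera-Formicidae", "Coleoptera", "Hemiptera", "Araneae")
_OTHERT_WEIGHTS = (0.667, 0.163, 0.089, 0.081)


def geometric_p_for_median(median: int) -> float:
    """Success probability of a geometric (support 1, 2, ...) whose sample
    median is ``median``.

    Solves ``(1-p)**(median - 1/2) = 1/2`` so the CDF crosses 0.5 midway
    between ``median-1`` and ``median``; with the crossing exactly at
    ``median`` the empirical median of large samples would straddle
    ``median`` and ``median+1`` instead of settling on ``median``.
    """
    if median < 1:
        raise ValueError("median must be >= 1")
    return 1.0 - 0.5 ** (1.0 / (median - 0.5))


def sharpness_noise_for_rho(rho: float) -> float:
    """Noise s.d. for the latent sharpness so that (log-area, sharpness)
    attain Spearman correlation ``rho``.

    For bivariate normal data the Spearman correlation relates to the
    Pearson correlation r by rho_S = (6/pi) asin(r/2); sharpness is a
    monotone (logistic) transform of ``z + eps`` with z the standardised
    log-area and eps ~ N(0, tau^2), which preserves Spearman, so
    tau = sqrt(1/r^2 - 1).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    return math.sqrt(1.0 / r**2 - 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the ground-truth generator."""

    n_sessions: int = 200
    frames_per_session: int = 2220  # ~1 h at 1.6 s/frame
    frame_interval_s: float = 1.6
    arrivals_per_session: float = 6.0  # visitors per ~1 h session
    class_mix: tuple[float, float, float] = (0.79, 0.11, 0.10)  # Hym/Dip/OtherT
    visit_median_frames: int = 7
    area_median: float = 0.028
    area_mean: float = 0.075
    sharpness_rho: float = 0.79  # target Spearman(area, sharpness)
    occlusion_prob: float = 0.05  # chance of an occlusion gap before a frame
    image_w: int = 850
    image_h: int = 800
    #: exact per-group individual counts; overrides arrivals and class mix
    n_individuals_per_group: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_sessions < 1 or self.frames_per_session < 1:
            raise ValueError("need at least one session and one frame")
        mean_visit = 1.0 / geometric_p_for_median(self.visit_median_frames)
        if mean_visit > self.frames_per_session:
            import warnings

            warnings.warn(
                "expected visit length exceeds session length; visits will be truncated",
                stacklevel=2,
            )

    @property
    def area_log_mu(self) -> float:
        return math.log(self.area_median)

    @property
    def area_log_sigma(self) -> float:
        # lognormal: mean = exp(mu + sigma^2/2)  =>  sigma from mean/median
        return math.sqrt(2.0 * math.log(self.area_mean / self.area_median))


@dataclass
class SyntheticDataset:
    """Generated ground truth plus per-box latent covariates."""

    annotations: list[GroundTruthAnnotation]  # arthropod + ROI boxes
    sequences: list[IndividualSequence]
    box_features: pd.DataFrame  # image_id, session_id, individual_id, frame_index, taxon, group, rel_area, sharpness_raw
    image_sizes: dict[str, tuple[int, int]]
    config: SynthConfig

    @property
    def n_images(self) -> int:
        """Number of annotated (arthropod-containing) images."""
        return len(self.image_sizes)

    def arthropod_annotations(self) -> list[GroundTruthAnnotation]:
        return [a for a in self.annotations if not a.is_roi]

    def background_image_ids(self, n: int, seed: int = 0) -> list[str]:
        """Sample ``n`` frame ids that contain no arthropod, across sessions."""
        rng = np.random.default_rng(seed)
        annotated = set(self.image_sizes)
        out: list[str] = []
        guard = 0
        while len(out) < n:
            s = int(rng.integers(self.config.n_sessions))
            f = int(rng.integers(self.config.frames_per_session))
            iid = _image_id(_session_id(s), f)
            if iid not in annotated and iid not in out:
                out.append(iid)
            guard += 1
            if guard > 100 * n + 1000:
                raise RuntimeError("could not find enough background frames")
        return out


def _session_id(i: int) -> str:
    return f"S{i:03d}"


def _image_id(session_id: str, frame: int) -> str:
    return f"{session_id}_{frame:06d}.jpg"


def _sample_visit_frames(
    rng: np.random.Generator, n_boxes: int, start: int, last_frame: int, occlusion_prob: float
) -> list[int]:
    """Frame indices of one visit: consecutive, with occasional short gaps."""
    frames = [start]
    f = start
    for _ in range(n_boxes - 1):
        f += 1
        if rng.random() < occlusion_prob:
            f += int(rng.integers(1, 4))  # occluded for 1-3 frames
        if f > last_frame:
            break
        frames.append(f)
    return frames


def gen_ground_truth(cfg: SynthConfig) -> SyntheticDataset:
    """Generate sessions of annotated frames under ``cfg``.

    Deterministic for a fixed ``cfg.seed``.  Each annotated image carries
    exactly one ROI box (the target flower, a fixed central region of the
    frame) besides its arthropod boxes.
    """
    rng = np.random.default_rng(cfg.seed)
    W, H = cfg.image_w, cfg.image_h
    p_visit = geometric_p_for_median(cfg.visit_median_frames)
    mu, sigma = cfg.area_log_mu, cfg.area_log_sigma
    noise_sd = sharpness_noise_for_rho(cfg.sharpness_rho)
    roi_box = Box(round(W * 0.15), round(H * 0.15), round(W * 0.7), round(H * 0.7))

    # --- roster of individuals: (session index, group) -------------------
    roster: list[tuple[int, str]] = []
    if cfg.n_individuals_per_group is not None:
        for group, count in cfg.n_individuals_per_group.items():
            for j in range(count):
                roster.append((int(rng.integers(cfg.n_sessions)), group))
    else:
        for s in range(cfg.n_sessions):
            for _ in range(rng.poisson(cfg.arrivals_per_session)):
                g = GROUPS[rng.choice(3, p=np.asarray(cfg.class_mix))]
                roster.append((s, g))
    if not roster:
        raise ValueError("configuration produced zero individuals")

    annotations: list[GroundTruthAnnotation] = []
    feat_rows: list[dict] = []
    annotated_images: set[str] = set()
    last_frame = cfg.frames_per_session - 1

    for ind_counter, (s, group) in enumerate(roster):
        session_id = _session_id(s)
        individual_id = f"ind{ind_counter:05d}"
        if group == "OtherT":
            taxon = str(rng.choice(_OTHERT_TAXA, p=np.asarray(_OTHERT_WEIGHTS)))
        else:
            taxon = group

        n_boxes = int(min(rng.geometric(p_visit), cfg.frames_per_session))
        start = int(rng.integers(0, max(1, cfg.frames_per_session - n_boxes + 1)))
        frames = _sample_visit_frames(rng, n_boxes, start, last_frame, cfg.occlusion_prob)

        # per-individual base size, small per-frame variation
        log_area_base = rng.normal(mu, sigma)
        aspect = math.exp(rng.normal(0.0, 0.3))
        cx = rng.uniform(roi_box.x_min, roi_box.x_max)
        cy = rng.uniform(roi_box.y_min, roi_box.y_max)

        for f in frames:
            log_area = log_area_base + rng.normal(0.0, 0.1)
            area = min(math.exp(log_area), 0.9)
            w = math.sqrt(area * W * H * aspect)
            h = math.sqrt(area * W * H / aspect)
            w = float(min(max(w, 2.0), W - 1.0))
            h = float(min(max(h, 2.0), H - 1.0))
            # drift, clamped so the box stays inside the frame
            cx = float(np.clip(cx + rng.normal(0.0, 8.0), w / 2, W - w / 2))
            cy = float(np.clip(cy + rng.normal(0.0, 8.0), h / 2, H - h / 2))
            x = max(0.0, min(cx - w / 2, W - w))
            y = max(0.0, min(cy - h / 2, H - h))
            box = Box(x, y, w, h)

            z = (log_area - mu) / sigma
            sharp_latent = 1.0 / (1.0 + math.exp(-(z + rng.normal(0.0, noise_sd))))
            image_id = _image_id(session_id, f)
            annotations.append(
                GroundTruthAnnotation(
                    image_id=image_id,
                    session_id=session_id,
                    frame_index=f,
                    box=box,
                    taxon=taxon,
                    individual_id=individual_id,
                )
            )
            annotated_images.add(image_id)
            feat_rows.append(
                {
                    "image_id": image_id,
                    "session_id": session_id,
                    "individual_id": individual_id,
                    "frame_index": f,
                    "taxon": taxon,
                    "group": group,
                    "rel_area": box.area / (W * H),
                    "sharpness_raw": 500.0 * sharp_latent,
                }
            )

    # one ROI box per annotated image
    for image_id in sorted(annotated_images):
        session_id, frame_s = image_id.rsplit("_", 1)
        annotations.append(
            GroundTruthAnnotation(
                image_id=image_id,
                session_id=session_id,
                frame_index=int(frame_s.split(".")[0]),
                box=roi_box,
                is_roi=True,
            )
        )

    sequences = assemble_individuals(annotations)
    return SyntheticDataset(
        annotations=annotations,
        sequences=sequences,
        box_features=pd.DataFrame(feat_rows),
        image_sizes={iid: (W, H) for iid in annotated_images},
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Detector simulation
# ---------------------------------------------------------------------------


def default_confusion(
    self_mass: float = 0.78,
    hym_dip_mass: float = 0.13,
) -> pd.DataFrame:
    """Row-stochastic 8x8 label-confusion matrix over the fine taxa.

    Diagonal mass ``self_mass``; the Hymenoptera and Diptera rows place
    ``hym_dip_mass`` on each other (mimicry-driven cross-order confusion);
    the remainder of each row is spread evenly over the other labels.
    """
    n = len(TAXA)
    cm = pd.DataFrame(0.0, index=list(TAXA), columns=list(TAXA))
    for t in TAXA:
        cm.loc[t, t] = self_mass
        rest = [u for u in TAXA if u != t]
        if t == "Hymenoptera":
            cm.loc[t, "Diptera"] = hym_dip_mass
            rest = [u for u in rest if u != "Diptera"]
            spread = 1.0 - self_mass - hym_dip_mass
        elif t == "Diptera":
            cm.loc[t, "Hymenoptera"] = hym_dip_mass
            rest = [u for u in rest if u != "Hymenoptera"]
            spread = 1.0 - self_mass - hym_dip_mass
        else:
            spread = 1.0 - self_mass
        for u in rest:
            cm.loc[t, u] = spread / len(rest)
    return cm


@dataclass
class DetectorModel:
    """Behavioural model of a simulated object detector.

    Localisation operates in one of two modes:

    * per-box logistic (default): each ground-truth box is detected with
      probability ``sigmoid(b0 + b_area * z_area + b_sharp * (2s - 1))``
      where ``z_area`` is the standardised log relative area and ``s`` the
      latent sharpness in (0, 1) — bigger, sharper arthropods are found
      more often;
    * injected sequence rates: ``seq_localisation_probs`` maps each group to
      the probability that an individual is localised at all; detected
      individuals then get a Binomial subset of their boxes (>= 1 forced).
    """

    seq_localisation_probs: Mapping[str, float] | None = None
    box_hit_rate: float = 0.6  # per-box detection prob within a localised sequence
    logit_intercept: float = 0.4
    logit_area: float = 1.2
    logit_sharp: float = 0.8
    confusion: pd.DataFrame = field(default_factory=default_confusion)
    conf_correct: tuple[float, float] = (6.0, 2.5)  # Beta params, mean ~0.71
    conf_incorrect: tuple[float, float] = (2.5, 3.5)  # Beta params, mean ~0.42
    fp_rate: float = 0.08  # expected background FPs per image
    box_jitter: float = 0.06  # relative centre shift / log-size jitter s.d.
    duplicate_rate: float = 0.0  # chance of a second, lower-conf box per hit
    seed: int = 0

    def __post_init__(self) -> None:
        rowsums = self.confusion.sum(axis=1)
        if not np.allclose(rowsums, 1.0):
            raise ValueError("confusion rows must sum to 1")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


def _jitter_box(rng: np.random.Generator, box: Box, scale: float, W: int, H: int) -> Box:
    w = box.width * math.exp(rng.normal(0.0, scale))
    h = box.height * math.exp(rng.normal(0.0, scale))
    cx = box.x_min + box.width / 2 + rng.normal(0.0, scale * box.width)
    cy = box.y_min + box.height / 2 + rng.normal(0.0, scale * box.height)
    w = float(min(max(w, 2.0), W - 1.0))
    h = float(min(max(h, 2.0), H - 1.0))
    cx = float(np.clip(cx, w / 2, W - w / 2))
    cy = float(np.clip(cy, h / 2, H - h / 2))
    x = max(0.0, min(cx - w / 2, W - w))
    y = max(0.0, min(cy - h / 2, H - h))
    return Box(x, y, w, h)


def simulate_detector(
    dataset: SyntheticDataset,
    model: DetectorModel,
    fp_image_ids: Sequence[str] | None = None,
) -> list[Prediction]:
    """Emit raw (pre-NMS) predictions for a synthetic dataset.

    Background false positives are generated as a Poisson process over
    ``fp_image_ids`` (default: every annotated image).  Deterministic for a
    fixed ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    cfg = dataset.config
    W, H = cfg.image_w, cfg.image_h
    feats = dataset.box_features
    labels = list(model.confusion.columns)
    conf_rows = {t: model.confusion.loc[t].to_numpy() for t in model.confusion.index}

    preds: list[Prediction] = []
    anns_by_key = {
        (a.session_id, a.individual_id, a.frame_index): a
        for a in dataset.annotations
        if not a.is_roi
    }
    mu, sigma = cfg.area_log_mu, cfg.area_log_sigma

    # group feature rows per individual, preserving frame order
    for (session_id, individual_id), g in feats.groupby(["session_id", "individual_id"], sort=True):
        g = g.sort_values("frame_index")
        if model.seq_localisation_probs is not None:
            p_seq = model.seq_localisation_probs[g["group"].iloc[0]]
            if rng.random() >= p_seq:
                continue  # individual entirely missed
            hits = rng.random(len(g)) < model.box_hit_rate
            if not hits.any():
                hits[rng.integers(len(g))] = True
        else:
            z = (np.log(g["rel_area"].to_numpy()) - mu) / sigma
            s = g["sharpness_raw"].to_numpy() / 500.0
            logit = model.logit_intercept + model.logit_area * z + model.logit_sharp * (2 * s - 1)
            hits = rng.random(len(g)) < 1.0 / (1.0 + np.exp(-logit))

        for row, hit in zip(g.itertuples(index=False), hits):
            if not hit:
                continue
            ann = anns_by_key[(session_id, individual_id, int(row.frame_index))]
            box = _jitter_box(rng, ann.box, model.box_jitter, W, H)
            label = labels[int(rng.choice(len(labels), p=conf_rows[row.taxon]))]
            a, b = model.conf_correct if label == row.taxon else model.conf_incorrect
            conf = float(rng.beta(a, b))
            preds.append(Prediction(image_id=row.image_id, box=box, label=label, confidence=conf))
            if rng.random() < model.duplicate_rate:
                dup = _jitter_box(rng, ann.box, model.box_jitter, W, H)
                preds.append(
                    Prediction(
                        image_id=row.image_id,
                        box=dup,
                        label=label,
                        confidence=conf * float(rng.uniform(0.5, 0.9)),
                    )
                )

    # background false positives
    if model.fp_rate > 0:
        images = list(fp_image_ids) if fp_image_ids is not None else sorted(dataset.image_sizes)
        for image_id in images:
            for _ in range(rng.poisson(model.fp_rate)):
                area = min(math.exp(rng.normal(mu, sigma)), 0.5)
                aspect = math.exp(rng.normal(0.0, 0.3))
                w = float(min(max(math.sqrt(area * W * H * aspect), 2.0), W - 1.0))
                h = float(min(max(math.sqrt(area * W * H / aspect), 2.0), H - 1.0))
                x = float(rng.uniform(0, W - w))
                y = float(rng.uniform(0, H - h))
                label = str(rng.choice(list(TAXA)))
                conf = float(rng.beta(1.8, 6.0))
                preds.append(
                    Prediction(image_id=image_id, box=Box(x, y, w, h), label=label, confidence=conf)
                )
    return preds


# ---------------------------------------------------------------------------
# Blur fixtures
# ---------------------------------------------------------------------------


def gen_blur_patches(
    n: int,
    blur_levels: Sequence[float],
    size: int = 33,
    seed: int = 0,
) -> np.ndarray:
    """Textured noise patches rendered at increasing Gaussian blur.

    Returns an array of shape ``(n, len(blur_levels), size, size)`` where
    patch ``[i, j]`` is patch ``i`` blurred with sigma ``blur_levels[j]``
    (sigma 0 = the original).  By construction, larger sigma means lower
    true sharpness, giving fixtures with a known focus ordering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    out = np.empty((n, len(blur_levels), size, size))
    for i in range(n):
        base = rng.standard_normal((size, size))
        for j, sigma in enumerate(blur_levels):
            out[i, j] = base if sigma == 0 else gaussian_filter(base, sigma)
    return out
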