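"""End-to-end evaluation runs: annotations + predictions -> report bundle.

Orchestrates filter -> NMS (optionally grid-searched) -> matching -> frame
metrics -> sequence metrics -> covariate statistics, and writes deterministic
CSV/JSON reports.  Images that appear in the prediction stream but hold no
ground-truth box are treated as background frames and get their own FPPI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (
    FilterRules,
    GroundTruthAnnotation,
    Prediction,
    assemble_individuals,
    filter_dataset,
    read_annotations_csv,
    read_predictions_csv,
)
from .frame_metrics import (
    DEFAULT_NMS_GRID,
    GridSearchResult,
    auc_pr,
    fppi,
    grid_search_nms,
    pr_f1_curve,
)
from .geometry import NmsConfig, nms
from .matching import MatchResult, match_dataset, matches_to_frame
from .features_stats import (
    binomial_test_one_tailed,
    normalize_sharpness,
    permutation_test,
    spearman_rho,
)
from .sequence_metrics import (
    assign_labels_max_conf,
    confusion_matrix,
    confusion_percentages,
    localise_individuals,
    metrics_table,
)

__all__ = ["RunConfig", "EvaluationReport", "run_evaluation"]


@dataclass
class RunConfig:
    """Configuration of one evaluation run.

    ``features`` optionally points to a per-box covariate CSV (columns
    ``session_id, individual_id, frame_index, rel_area, sharpness_raw``);
    with it, the run adds permutation tests of area/sharpness by
    localisation and classification outcome and the area-sharpness Spearman
    correlation.
    """

    annotations: str | Path = ""
    predictions: str | Path = ""
    output_dir: str | Path | None = None
    features: str | Path | None = None
    eval_iou: float = 0.5
    nms_grid: Sequence[float] = DEFAULT_NMS_GRID
    run_grid_search: bool = True
    nms_config: NmsConfig | None = None  # used when grid search is disabled
    filter_rules: FilterRules = field(default_factory=FilterRules)
    grouping: Mapping[str, str] | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eval_iou < 1.0:
            raise ValueError("eval_iou must be in (0, 1)")
        if not self.run_grid_search and self.nms_config is None:
            raise ValueError("grid search disabled but no fixed NmsConfig given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a declarative YAML file.

        Recognised keys match the dataclass fields; ``nms_config`` may be
        given as a ``{nms_iou: ..., conf_threshold: ...}`` mapping and
        ``filter_rules`` as ``{exclude_taxa: [...], drop_unknown: ...,
        drop_co_occurring: ...}``.
        """
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "nms_config" in data and data["nms_config"] is not None:
            data["nms_config"] = NmsConfig(**data["nms_config"])
        if "filter_rules" in data:
            fr = dict(data["filter_rules"])
            if "exclude_taxa" in fr:
                fr["exclude_taxa"] = frozenset(fr["exclude_taxa"])
            data["filter_rules"] = FilterRules(**fr)
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class EvaluationReport:
    """All artefacts of one run, as in-memory tables."""

    filter_log: dict
    grid_search: GridSearchResult | None
    nms_config: NmsConfig
    curve: pd.DataFrame
    auc: float
    fppi_arthropod_images: float
    fppi_background_images: float | None
    n_arthropod_images: int
    n_background_images: int
    box_localisation_fraction: float
    confusion: pd.DataFrame
    confusion_pct: pd.DataFrame
    metrics: pd.DataFrame
    match_table: pd.DataFrame
    stats: dict
    config_echo: dict


def _box_stats(
    gts: Sequence[GroundTruthAnnotation],
    results: Sequence[MatchResult],
    features: pd.DataFrame | None,
    n_perm: int,
    seed: int,
) -> tuple[dict, pd.DataFrame | None]:
    """Covariate contrasts + misclassification-direction binomial tests."""
    stats: dict = {}

    # box-level classification asymmetry: among mislabelled boxes of each of
    # the two focal orders, the share going to the other order vs chance 1/7
    for src, dst in (("Hymenoptera", "Diptera"), ("Diptera", "Hymenoptera")):
        mis = [
            p.label
            for r in results
            for p, g, _ in r.tp_pairs
            if g.taxon == src and p.label != src
        ]
        if mis:
            k = sum(1 for lab in mis if lab == dst)
            stats[f"box_mis_{src}_to_{dst}"] = {
                "k": k,
                "n": len(mis),
                "share": k / len(mis),
                "p_value": binomial_test_one_tailed(k, len(mis), 1.0 / 7.0),
            }

    if features is None:
        return stats, None

    feats = features.copy()
    key = ["session_id", "individual_id", "frame_index"]
    tp_keys = {
        (g.session_id, g.individual_id, g.frame_index): p.label == g.taxon
        for r in results
        for p, g, _ in r.tp_pairs
    }
    feats["localised"] = [
        tuple(k) in tp_keys for k in feats[key].itertuples(index=False, name=None)
    ]
    feats["correctly_classified"] = [
        tp_keys.get(tuple(k)) for k in feats[key].itertuples(index=False, name=None)
    ]
    feats["sharpness_norm"] = normalize_sharpness(feats["sharpness_raw"].to_numpy())

    rho = spearman_rho(feats["rel_area"], feats["sharpness_norm"])
    stats["spearman_area_sharpness"] = rho

    loc = feats[feats["localised"]]
    unloc = feats[~feats["localised"]]
    contrasts = {
        "localised_vs_not": (loc, unloc),
    }
    correct = loc[loc["correctly_classified"] == True]  # noqa: E712
    wrong = loc[loc["correctly_classified"] == False]  # noqa: E712
    if len(correct) and len(wrong):
        contrasts["classified_vs_mis"] = (correct, wrong)
    for name, (ga, gb) in contrasts.items():
        if not len(ga) or not len(gb):
            continue
        for col in ("rel_area", "sharpness_norm"):
            r = permutation_test(ga[col], gb[col], n_perm=n_perm, seed=seed)
            stats[f"perm_{name}_{col}"] = {
                "delta_mean": r.delta_mean,
                "delta_median": r.delta_median,
                "p_mean": r.p_mean,
                "p_median": r.p_median,
                "n_perm": r.n_perm,
            }
    return stats, feats


def run_evaluation(
    cfg: RunConfig,
    gts: Sequence[GroundTruthAnnotation] | None = None,
    preds: Sequence[Prediction] | None = None,
) -> EvaluationReport:
    """Run the full evaluation; ``gts``/``preds`` may be passed in memory,
    otherwise they are read from the paths in ``cfg``.

    Deterministic: identical config, inputs and seed reproduce every output
    byte-for-byte.
    """
    if gts is None:
        gts = read_annotations_csv(cfg.annotations)
    if preds is None:
        preds = read_predictions_csv(cfg.predictions)
    features = pd.read_csv(cfg.features) if cfg.features else None

    kept, flog = filter_dataset(gts, cfg.filter_rules)
    arthropods = [a for a in kept if not a.is_roi]
    sequences = assemble_individuals(kept, cfg.grouping)

    gt_images = {a.image_id for a in arthropods}
    pred_images = {p.image_id for p in preds}
    background_images = sorted(pred_images - gt_images)
    arthropod_images = sorted(gt_images)

    # --- NMS selection ---------------------------------------------------
    grid_result: GridSearchResult | None = None
    if cfg.run_grid_search:
        grid_result = grid_search_nms(
            arthropods,
            [p for p in preds if p.image_id in gt_images],
            grid=cfg.nms_grid,
            eval_iou=cfg.eval_iou,
        )
        nms_cfg = grid_result.best_config
    else:
        nms_cfg = cfg.nms_config  # type: ignore[assignment]

    from collections import defaultdict

    preds_by: dict[str, list[Prediction]] = defaultdict(list)
    for p in preds:
        preds_by[p.image_id].append(p)

    sweep_cfg = NmsConfig(nms_iou=nms_cfg.nms_iou, conf_threshold=0.0)
    sweep_preds = [q for ps in preds_by.values() for q in nms(ps, sweep_cfg)]
    final_preds = [q for q in sweep_preds if q.confidence >= nms_cfg.conf_threshold]

    # --- matching ---------------------------------------------------------
    sweep_results = match_dataset(
        arthropods,
        [q for q in sweep_preds if q.image_id in gt_images],
        eval_iou=cfg.eval_iou,
        image_ids=arthropod_images,
    )
    results = match_dataset(
        arthropods,
        [q for q in final_preds if q.image_id in gt_images],
        eval_iou=cfg.eval_iou,
        image_ids=arthropod_images,
    )
    bg_results = match_dataset(
        [],
        [q for q in final_preds if q.image_id not in gt_images],
        eval_iou=cfg.eval_iou,
        image_ids=background_images,
    )

    total_gt = len(arthropods)
    curve_pts = pr_f1_curve(sweep_results, total_gt)
    curve = pd.DataFrame(
        [
            {"conf_threshold": c.conf_threshold, "precision": c.precision, "recall": c.recall, "f1": c.f1}
            for c in curve_pts
        ]
    )
    n_tp = sum(r.n_tp for r in results)
    box_loc_fraction = n_tp / total_gt if total_gt else float("nan")

    # --- sequence level ---------------------------------------------------
    outcomes = localise_individuals(sequences, results)
    outcomes = assign_labels_max_conf(outcomes, results, cfg.grouping)
    cm = confusion_matrix(outcomes)
    metrics = metrics_table(cm)

    # --- statistics -------------------------------------------------------
    stats, feats = _box_stats(arthropods, results, features, cfg.n_perm, cfg.seed)

    # sequence-level misclassification direction vs chance 1/2
    for src, dst, other in (
        ("Hymenoptera", "Diptera", "OtherT"),
        ("Diptera", "Hymenoptera", "OtherT"),
    ):
        k = int(cm.loc[src, dst])
        n = k + int(cm.loc[src, other])
        if n:
            stats[f"seq_mis_{src}_to_{dst}"] = {
                "k": k,
                "n": n,
                "share": k / n,
                "p_value": binomial_test_one_tailed(k, n, 0.5),
            }

    report = EvaluationReport(
        filter_log=vars(flog) | {"total_removed": flog.total_removed},
        grid_search=grid_result,
        nms_config=nms_cfg,
        curve=curve,
        auc=auc_pr(curve_pts),
        fppi_arthropod_images=fppi(results),
        fppi_background_images=fppi(bg_results) if background_images else None,
        n_arthropod_images=len(arthropod_images),
        n_background_images=len(background_images),
        box_localisation_fraction=box_loc_fraction,
        confusion=cm,
        confusion_pct=confusion_percentages(cm),
        metrics=metrics,
        match_table=matches_to_frame(results),
        stats=stats,
        config_echo={
            "version": __version__,
            "eval_iou": cfg.eval_iou,
            "nms_iou": nms_cfg.nms_iou,
            "conf_threshold": nms_cfg.conf_threshold,
            "grid_searched": cfg.run_grid_search,
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
        },
    )
    if cfg.output_dir is not None:
        _write_report(report, Path(cfg.output_dir), feats)
    return report


def _write_report(report: EvaluationReport, out: Path, feats: pd.DataFrame | None) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if report.grid_search is not None:
        report.grid_search.table.to_csv(out / "grid_search.csv", index=False)
    report.curve.to_csv(out / "curve.csv", index=False)
    report.confusion.to_csv(out / "confusion_counts.csv")
    report.confusion_pct.to_csv(out / "confusion_pct.csv")
    report.metrics.to_csv(out / "metrics.csv")
    report.match_table.to_csv(out / "matches.csv", index=False)
    if feats is not None:
        feats.to_csv(out / "features.csv", index=False)
    summary = {
        "config": report.config_echo,
        "filter_log": report.filter_log,
        "auc": report.auc,
        "max_f1": float(report.curve["f1"].max()),
        "fppi_arthropod_images": report.fppi_arthropod_images,
        "fppi_background_images": report.fppi_background_images,
        "n_arthropod_images": report.n_arthropod_images,
        "n_background_images": report.n_background_images,
        "box_localisation_fraction": report.box_localisation_fraction,
        "stats": report.stats,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "stats.json").write_text(json.dumps(report.stats, indent=2, sort_keys=True))
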