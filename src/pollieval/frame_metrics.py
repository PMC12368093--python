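"""Frame-level detection metrics: P/R/F1-confidence curves, PR-AUC, the NMS
grid search, and false positives per image (FPPI).

Frames are treated as independent here — an arthropod box in one frame is
one detection target, irrespective of the time-lapse sequence it belongs to.
The confidence sweep evaluates every unique observed confidence as a
threshold, so the curve is exact rather than sampled on a fixed grid.

Because matching is greedy in descending confidence, a prediction's TP/FP
status does not depend on lower-confidence predictions; matching once with
all predictions retained and accumulating counts over the sorted confidences
therefore yields exactly the per-threshold re-evaluation (a ground truth
whose only matching prediction falls below the threshold reverts to FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GroundTruthAnnotation, Prediction
from .geometry import NmsConfig, nms
from .matching import MatchResult, match_dataset

__all__ = [
    "CurvePoint",
    "GridSearchResult",
    "pr_f1_curve",
    "auc_pr",
    "grid_search_nms",
    "fppi",
    "plot_curves",
]

DEFAULT_NMS_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass(frozen=True)
class CurvePoint:
    """Precision/recall/F1 at one confidence threshold."""

    conf_threshold: float
    precision: float
    recall: float
    f1: float


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0.0 else 2.0 * p * r / (p + r)


def pr_f1_curve(match_results: Sequence[MatchResult], total_gt: int) -> list[CurvePoint]:
    """Precision/recall/F1 at every unique observed confidence.

    ``match_results`` must come from matching with *all* predictions
    retained (confidence threshold 0).  At a threshold t, TP = matched
    predictions with confidence >= t, FP = unmatched ones with confidence
    >= t; precision = TP/(TP+FP) (0 when nothing is retained), recall =
    TP/``total_gt``.  Thresholds are returned in descending order.
    """
    if total_gt <= 0:
        raise ValueError("total_gt must be positive")
    confs: list[float] = []
    is_tp: list[bool] = []
    for r in match_results:
        for p, _g, _v in r.tp_pairs:
            confs.append(p.confidence)
            is_tp.append(True)
        for p in r.fp:
            confs.append(p.confidence)
            is_tp.append(False)
    if not confs:
        return [CurvePoint(conf_threshold=1.0, precision=0.0, recall=0.0, f1=0.0)]

    conf_arr = np.asarray(confs)
    tp_arr = np.asarray(is_tp, dtype=float)
    order = np.argsort(-conf_arr, kind="stable")
    conf_sorted = conf_arr[order]
    cum_tp = np.cumsum(tp_arr[order])
    cum_fp = np.cumsum(1.0 - tp_arr[order])

    points = []
    # last index of each distinct confidence value in the descending sort
    for i in range(len(conf_sorted)):
        if i + 1 < len(conf_sorted) and conf_sorted[i + 1] == conf_sorted[i]:
            continue
        tp, fp = cum_tp[i], cum_fp[i]
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / total_gt
        points.append(
            CurvePoint(
                conf_threshold=float(conf_sorted[i]),
                precision=float(precision),
                recall=float(recall),
                f1=_f1(float(precision), float(recall)),
            )
        )
    return points


def auc_pr(curve: Sequence[CurvePoint]) -> float:
    """Area under the precision-recall curve by trapezoidal integration.

    Points are sorted by recall; an anchor ``(recall 0, precision of the
    highest-threshold point)`` is prepended.  No extrapolation beyond the
    maximum achieved recall, and no precision-envelope interpolation — the
    raw trapezoid is documented so results are comparable.
    """
    if not curve:
        raise ValueError("empty curve")
    anchor_p = max(curve, key=lambda c: c.conf_threshold).precision
    pts = sorted([(c.recall, c.precision) for c in curve])
    recalls = np.array([0.0] + [r for r, _ in pts])
    precisions = np.array([anchor_p] + [p for _, p in pts])
    return float(np.trapezoid(precisions, recalls))


@dataclass
class GridSearchResult:
    """Outcome of the NMS hyperparameter grid search.

    ``table`` has one row per ``nms_iou`` with the best confidence
    threshold, the max F1 there, and the PR-AUC of that configuration's
    curve; ``best_*`` is the global argmax by F1 (ties take the lower
    ``nms_iou``).
    """

    table: pd.DataFrame
    best_nms_iou: float
    best_conf: float
    max_f1: float
    best_auc: float

    @property
    def best_config(self) -> NmsConfig:
        return NmsConfig(nms_iou=self.best_nms_iou, conf_threshold=self.best_conf)


def grid_search_nms(
    gts: Iterable[GroundTruthAnnotation],
    raw_preds: Iterable[Prediction],
    grid: Sequence[float] = DEFAULT_NMS_GRID,
    eval_iou: float = 0.5,
    image_ids: Sequence[str] | None = None,
) -> GridSearchResult:
    """Sweep ``nms_iou`` over ``grid`` on un-suppressed predictions.

    For each grid value: suppress (confidence threshold 0 so the curve can
    sweep confidence afterwards), match class-agnostically at ``eval_iou``,
    build the F1-confidence curve, and record the max F1 with its confidence
    plus the PR-AUC.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty NMS grid")
    gts = [g for g in gts if not g.is_roi]
    raw_preds = list(raw_preds)
    total_gt = len(gts)

    from collections import defaultdict

    preds_by: dict[str, list[Prediction]] = defaultdict(list)
    for p in raw_preds:
        preds_by[p.image_id].append(p)

    rows = []
    for nms_iou in grid:
        cfg = NmsConfig(nms_iou=nms_iou, conf_threshold=0.0)
        suppressed = [q for preds in preds_by.values() for q in nms(preds, cfg)]
        results = match_dataset(gts, suppressed, eval_iou=eval_iou, image_ids=image_ids)
        curve = pr_f1_curve(results, total_gt)
        best = max(curve, key=lambda c: (c.f1, c.conf_threshold))
        rows.append(
            {
                "nms_iou": nms_iou,
                "best_conf": best.conf_threshold,
                "max_f1": best.f1,
                "auc": auc_pr(curve),
            }
        )
    table = pd.DataFrame(rows)
    i_best = int(table["max_f1"].idxmax())  # ties -> first (lowest nms_iou)
    return GridSearchResult(
        table=table,
        best_nms_iou=float(table.loc[i_best, "nms_iou"]),
        best_conf=float(table.loc[i_best, "best_conf"]),
        max_f1=float(table.loc[i_best, "max_f1"]),
        best_auc=float(table.loc[i_best, "auc"]),
    )


def fppi(match_results: Sequence[MatchResult]) -> float:
    """False positives per image: total FP count / number of images.

    On arthropod-containing images FPs are the unmatched predictions at the
    evaluation IoU; on background-only images every prediction is a FP.
    """
    if not match_results:
        raise ValueError("fppi requires at least one image")
    return sum(r.n_fp for r in match_results) / len(match_results)


def plot_curves(curve: Sequence[CurvePoint], path=None):
    """F1-confidence and precision-recall panels for one configuration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    conf = [c.conf_threshold for c in curve]
    ax1.plot(conf, [c.f1 for c in curve])
    ax1.set_xlabel("confidence threshold")
    ax1.set_ylabel("F1")
    pts = sorted([(c.recall, c.precision) for c in curve])
    ax2.plot([r for r, _ in pts], [p for _, p in pts])
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    for ax in (ax1, ax2):
        ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
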