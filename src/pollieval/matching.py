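"""Assignment of predictions to ground-truth boxes at an evaluation IoU.

Per image, predictions (already NMS-processed) are matched one-to-one to
ground-truth boxes by a greedy pass in descending confidence: each prediction
claims the still-unmatched ground truth with the highest IoU, provided that
IoU reaches ``eval_iou`` (and, in class-aware mode, the labels agree).
Unmatched predictions are false positives (this includes duplicate detections
of an already-claimed ground truth); unmatched ground truths are false
negatives.  Localisation evaluation is class-agnostic — a box counts as found
regardless of the predicted label.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import GroundTruthAnnotation, Prediction
from .geometry import iou

__all__ = ["MatchResult", "match_image", "match_dataset", "matches_to_frame"]


@dataclass
class MatchResult:
    """Box-level TP/FP/FN for one image at a given eval-IoU.

    ``tp_pairs`` holds ``(prediction, ground_truth, iou)`` triples; every
    prediction and every ground truth appears in at most one triple.
    """

    image_id: str
    tp_pairs: list[tuple[Prediction, GroundTruthAnnotation, float]] = field(default_factory=list)
    fp: list[Prediction] = field(default_factory=list)
    fn: list[GroundTruthAnnotation] = field(default_factory=list)
    eval_iou: float = 0.5

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


def match_image(
    gts: Sequence[GroundTruthAnnotation],
    preds: Sequence[Prediction],
    eval_iou: float = 0.5,
    class_aware: bool = False,
    image_id: str | None = None,
) -> MatchResult:
    """Greedy one-to-one matching for a single image.

    Predictions are visited in descending confidence (ties keep input
    order); each takes the unmatched ground truth of maximal IoU >=
    ``eval_iou`` (ties broken by the lowest ground-truth index).  In
    class-aware mode a pair additionally requires ``pred.label ==
    gt.taxon``.
    """
    if not 0.0 < eval_iou < 1.0:
        raise ValueError(f"eval_iou must be in (0, 1), got {eval_iou}")
    gts = [g for g in gts if not g.is_roi]
    if image_id is None:
        image_id = gts[0].image_id if gts else (preds[0].image_id if preds else "")

    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    taken = [False] * len(gts)
    result = MatchResult(image_id=image_id, eval_iou=eval_iou)
    for pi in order:
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            if class_aware and p.label != g.taxon:
                continue
            v = iou(p.box, g.box)
            if v >= eval_iou and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            result.tp_pairs.append((p, gts[best_j], best_iou))
        else:
            result.fp.append(p)
    result.fn = [g for j, g in enumerate(gts) if not taken[j]]
    return result


def match_dataset(
    gts: Iterable[GroundTruthAnnotation],
    preds: Iterable[Prediction],
    eval_iou: float = 0.5,
    image_ids: Sequence[str] | None = None,
    class_aware: bool = False,
) -> list[MatchResult]:
    """Match every image of a dataset; one :class:`MatchResult` per image.

    ``image_ids`` fixes the image universe (so background-only frames with
    no ground truth and no predictions still yield an empty result, and a
    prediction on an image outside the universe raises).  By default the
    universe is the union of images seen in ``gts`` and ``preds``.
    """
    gts_by: dict[str, list[GroundTruthAnnotation]] = defaultdict(list)
    for g in gts:
        if not g.is_roi:
            gts_by[g.image_id].append(g)
    preds_by: dict[str, list[Prediction]] = defaultdict(list)
    for p in preds:
        preds_by[p.image_id].append(p)

    if image_ids is None:
        universe = sorted(set(gts_by) | set(preds_by))
    else:
        universe = list(image_ids)
        unknown = set(preds_by) - set(universe)
        if unknown:
            raise KeyError(f"predictions reference unknown image_ids: {sorted(unknown)[:5]}")

    return [
        match_image(gts_by.get(i, []), preds_by.get(i, []), eval_iou, class_aware, image_id=i)
        for i in universe
    ]


def matches_to_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    """Flatten match results to a long table (one row per TP/FP/FN record)."""
    rows = []
    for r in results:
        for p, g, v in r.tp_pairs:
            rows.append(
                {
                    "image_id": r.image_id,
                    "kind": "TP",
                    "pred_label": p.label,
                    "confidence": p.confidence,
                    "gt_taxon": g.taxon,
                    "gt_individual_id": g.individual_id,
                    "iou": v,
                }
            )
        for p in r.fp:
            rows.append(
                {
                    "image_id": r.image_id,
                    "kind": "FP",
                    "pred_label": p.label,
                    "confidence": p.confidence,
                    "gt_taxon": "",
                    "gt_individual_id": "",
                    "iou": float("nan"),
                }
            )
        for g in r.fn:
            rows.append(
                {
                    "image_id": r.image_id,
                    "kind": "FN",
                    "pred_label": "",
                    "confidence": float("nan"),
                    "gt_taxon": g.taxon,
                    "gt_individual_id": g.individual_id,
                    "iou": float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["image_id", "kind", "pred_label", "confidence", "gt_taxon", "gt_individual_id", "iou"],
    )
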