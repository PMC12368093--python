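"""Box geometry: intersection-over-union and non-maximum suppression.

IoU is used twice in the evaluation, with different roles: as the NMS
suppression threshold (``nms_iou``, a post-processing hyperparameter swept in
a grid search) and as the match-acceptance threshold (``eval_iou``, fixed at
0.5 for the primary evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotations import Box, Prediction

__all__ = ["NmsConfig", "iou", "nms"]


@dataclass(frozen=True)
class NmsConfig:
    """Non-maximum-suppression hyperparameters.

    ``nms_iou``: overlap above which a lower-confidence box is suppressed.
    ``conf_threshold``: minimum confidence retained (applied before
    suppression, matching standard YOLO post-processing order).
    """

    nms_iou: float = 0.3
    conf_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nms_iou < 1.0:
            raise ValueError(f"nms_iou must be in (0, 1), got {self.nms_iou}")
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise ValueError(f"conf_threshold must be in [0, 1], got {self.conf_threshold}")


def iou(a: Box, b: Box) -> float:
    """Intersection area over union area; 0 for disjoint boxes, 1 for
    identical ones.  Symmetric."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(
    predictions: Sequence[Prediction],
    cfg: NmsConfig,
    class_agnostic: bool = True,
) -> list[Prediction]:
    """Greedy non-maximum suppression over one image's predictions.

    Predictions below ``cfg.conf_threshold`` are dropped first.  The
    remainder are visited in descending confidence (ties keep input order);
    each kept box suppresses any later box overlapping it with
    IoU > ``cfg.nms_iou`` (strict).  With ``class_agnostic=False``
    suppression only applies between boxes of the same label.  Output is
    sorted by descending confidence.
    """
    survivors = [p for p in predictions if p.confidence >= cfg.conf_threshold]
    # stable sort: equal confidences retain input order for determinism
    survivors.sort(key=lambda p: -p.confidence)
    kept: list[Prediction] = []
    for p in survivors:
        suppressed = any(
            (class_agnostic or k.label == p.label) and iou(k.box, p.box) > cfg.nms_iou
            for k in kept
        )
        if not suppressed:
            kept.append(p)
    return kept
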