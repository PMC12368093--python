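"""Sequence-level (per-individual) localisation and classification metrics.

An individual arthropod is a sequence of ground-truth boxes across a
time-lapse session.  Localisation succeeds for an individual (an
"arthropod-TP") if at least one of its boxes is matched by a prediction at
the evaluation IoU, regardless of the predicted labels — one good frame in
the visit is enough to register the floral visit.

Classification uses a maximum-confidence rule: among all matched boxes of a
sequence, the predicted label carried by the highest-confidence match is
assigned to the whole individual.  Selection runs over the fine detector
labels; collapsing to the coarse groups (Hymenoptera / Diptera / OtherT)
happens only afterwards.  Unlocalised individuals fall into a
background/false-negative (``Bg./FN``) column of the confusion matrix.

Metric conventions (chosen so a published confusion matrix and its printed
metric columns are mutually consistent):

* per-class recall      = diag_c / rowsum_c
* per-class precision   = diag_c / colsum_c  (Bg./FN is never a predicted class)
* per-class F1          = harmonic mean of that class's P and R
* per-class accuracy    = (N - FP_c - FN_c) / N,  FP_c = colsum_c - diag_c,
                          FN_c = rowsum_c - diag_c  (misses to Bg./FN included)
* overall P, accuracy   = class-size-weighted means
* overall recall        = sum(diag) / N  (equals the weighted mean of recalls)
* overall F1            = harmonic mean of overall P and overall R
* localisation recall   = localised / N (per class and overall)
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import DEFAULT_GROUPING, GROUPS, IndividualSequence, group_of
from .matching import MatchResult

__all__ = [
    "BACKGROUND",
    "SequenceOutcome",
    "localise_individuals",
    "assign_labels_max_conf",
    "confusion_matrix",
    "confusion_from_counts",
    "class_metrics",
    "overall_metrics",
    "metrics_table",
    "confusion_percentages",
]

#: Column name for unlocalised individuals (false negatives at sequence level).
BACKGROUND = "Bg./FN"


@dataclass
class SequenceOutcome:
    """Localisation/classification outcome for one individual."""

    individual_id: str
    session_id: str
    group: str
    localised: bool = False
    assigned_label: str | None = None  # coarse group after collapsing
    assigned_taxon: str | None = None  # fine label that won the max-conf rule
    max_confidence: float | None = None
    n_box_tp: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.session_id, self.individual_id)


def _tp_by_individual(
    match_results: Iterable[MatchResult],
) -> dict[tuple[str, str], list[tuple[float, int, str]]]:
    """Collect (confidence, frame_index, predicted label) of every box-TP,
    keyed by (session_id, individual_id) of the matched ground truth."""
    pools: dict[tuple[str, str], list[tuple[float, int, str]]] = defaultdict(list)
    for r in match_results:
        for p, g, _v in r.tp_pairs:
            pools[(g.session_id, g.individual_id)].append((p.confidence, g.frame_index, p.label))
    return pools


def localise_individuals(
    sequences: Sequence[IndividualSequence],
    match_results: Sequence[MatchResult],
) -> list[SequenceOutcome]:
    """Mark each individual localised iff >= 1 of its boxes is a box-TP.

    ``match_results`` should come from class-agnostic matching at the
    evaluation IoU.
    """
    pools = _tp_by_individual(match_results)
    out = []
    for s in sequences:
        tps = pools.get(s.key, [])
        out.append(
            SequenceOutcome(
                individual_id=s.individual_id,
                session_id=s.session_id,
                group=s.group,
                localised=len(tps) > 0,
                n_box_tp=len(tps),
            )
        )
    return out


def assign_labels_max_conf(
    outcomes: Sequence[SequenceOutcome],
    match_results: Sequence[MatchResult],
    grouping: Mapping[str, str] | None = None,
) -> list[SequenceOutcome]:
    """Label each localised individual by its highest-confidence box-TP.

    Ties at equal confidence go to the earliest frame (deterministic).  The
    fine label that wins is kept in ``assigned_taxon``; ``assigned_label``
    is its coarse group.
    """
    pools = _tp_by_individual(match_results)
    out = []
    for o in outcomes:
        o = SequenceOutcome(**vars(o))
        tps = pools.get(o.key, [])
        if tps:
            # max confidence; tie -> earliest frame
            conf, _frame, label = max(tps, key=lambda t: (t[0], -t[1]))
            o.localised = True
            o.n_box_tp = len(tps)
            o.max_confidence = conf
            o.assigned_taxon = label
            o.assigned_label = group_of(label, grouping)
        out.append(o)
    return out


def confusion_matrix(
    outcomes: Sequence[SequenceOutcome],
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Counts of (true group -> assigned group), with a ``Bg./FN`` column
    for unlocalised individuals.  Rows sum to the group sizes."""
    cm = pd.DataFrame(0, index=list(groups), columns=list(groups) + [BACKGROUND], dtype=int)
    for o in outcomes:
        col = o.assigned_label if (o.localised and o.assigned_label) else BACKGROUND
        cm.loc[o.group, col] += 1
    return cm


def confusion_from_counts(
    counts: Mapping[str, Sequence[int]],
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Build the confusion matrix from per-row counts
    ``{true_group: [pred_counts..., bg_fn]}`` (columns in ``groups`` order
    plus the Bg./FN column)."""
    cm = pd.DataFrame(
        [list(counts[g]) for g in groups],
        index=list(groups),
        columns=list(groups) + [BACKGROUND],
    )
    return cm.astype(int)


def confusion_percentages(cm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise percentage view (count / row total * 100)."""
    return cm.div(cm.sum(axis=1), axis=0) * 100.0


def class_metrics(cm: pd.DataFrame) -> pd.DataFrame:
    """Per-class metrics from a confusion matrix with a Bg./FN column.

    Columns: n_individuals, n_localised, localisation_recall, precision,
    recall, f1, accuracy.  Precision is NaN for a class never predicted.
    """
    groups = [c for c in cm.columns if c != BACKGROUND]
    n_total = int(cm.to_numpy().sum())
    rows = []
    for g in groups:
        rowsum = int(cm.loc[g].sum())
        colsum = int(cm[g].sum())
        diag = int(cm.loc[g, g])
        localised = rowsum - int(cm.loc[g, BACKGROUND]) if BACKGROUND in cm.columns else rowsum
        recall = diag / rowsum if rowsum else float("nan")
        precision = diag / colsum if colsum else float("nan")
        fp = colsum - diag
        fn = rowsum - diag
        rows.append(
            {
                "class": g,
                "n_individuals": rowsum,
                "n_localised": localised,
                "localisation_recall": localised / rowsum if rowsum else float("nan"),
                "precision": precision,
                "recall": recall,
                "f1": _harmonic(precision, recall),
                "accuracy": (n_total - fp - fn) / n_total if n_total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def overall_metrics(cm: pd.DataFrame) -> pd.Series:
    """Overall row: precision and accuracy weighted by class size, recall =
    pooled diagonal / N, F1 = harmonic mean of overall P and R."""
    per = class_metrics(cm)
    groups = [c for c in cm.columns if c != BACKGROUND]
    n = per["n_individuals"].sum()
    w = per["n_individuals"] / n
    precision = float((w * per["precision"]).sum())
    recall = float(sum(int(cm.loc[g, g]) for g in groups) / n)
    return pd.Series(
        {
            "n_individuals": int(n),
            "n_localised": int(per["n_localised"].sum()),
            "localisation_recall": float(per["n_localised"].sum() / n),
            "precision": precision,
            "recall": recall,
            "f1": _harmonic(precision, recall),
            "accuracy": float((w * per["accuracy"]).sum()),
        },
        name="Overall",
    )


def metrics_table(cm: pd.DataFrame) -> pd.DataFrame:
    """Per-class rows plus the Overall row (report layout)."""
    per = class_metrics(cm)
    overall = overall_metrics(cm).to_frame().T
    overall.index.name = per.index.name
    table = pd.concat([per, overall])
    table[["n_individuals", "n_localised"]] = table[["n_individuals", "n_localised"]].astype(int)
    return table


def _harmonic(p: float, r: float) -> float:
    if pd.isna(p) or pd.isna(r):
        return float("nan")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)
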