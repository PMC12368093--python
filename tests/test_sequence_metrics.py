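"""Individual-level localisation, max-confidence labelling, confusion and
metric tables."""

import numpy as np
import pandas as pd
import pytest

from pollieval.annotations import IndividualSequence, assemble_individuals
from pollieval.matching import MatchResult, match_dataset
from pollieval.sequence_metrics import (
    BACKGROUND,
    assign_labels_max_conf,
    class_metrics,
    confusion_from_counts,
    confusion_matrix,
    confusion_percentages,
    localise_individuals,
    metrics_table,
    overall_metrics,
)

from conftest import make_gt, make_pred


def _sequence(n_frames, taxon="Hymenoptera", individual_id="A", session_id="S0"):
    anns = [
        make_gt(0, 0, 10, 10, image_id=f"{session_id}_{f:06d}.jpg", session_id=session_id,
                frame_index=f, taxon=taxon, individual_id=individual_id)
        for f in range(n_frames)
    ]
    return assemble_individuals(anns)[0], anns


class TestLocaliseIndividuals:
    def test_one_matched_box_localises_sequence(self):
        seq, anns = _sequence(5)
        preds = [make_pred(0, 0, 10, 10, image_id=anns[2].image_id, confidence=0.7)]
        results = match_dataset(anns, preds)
        out = localise_individuals([seq], results)
        assert out[0].localised and out[0].n_box_tp == 1

    def test_unmatched_sequence_is_background(self):
        seq, anns = _sequence(3)
        out = localise_individuals([seq], match_dataset(anns, []))
        assert not out[0].localised and out[0].n_box_tp == 0

    def test_counts_all_tps(self):
        seq, anns = _sequence(4)
        preds = [make_pred(0, 0, 10, 10, image_id=a.image_id, confidence=0.5) for a in anns]
        out = localise_individuals([seq], match_dataset(anns, preds))
        assert out[0].n_box_tp == 4


class TestAssignLabels:
    def _outcomes(self, labelled_confs, taxon="Hymenoptera"):
        """labelled_confs: list of (label, confidence) per consecutive frame."""
        seq, anns = _sequence(len(labelled_confs), taxon=taxon)
        preds = [
            make_pred(0, 0, 10, 10, image_id=anns[i].image_id, label=lab, confidence=c)
            for i, (lab, c) in enumerate(labelled_confs)
        ]
        results = match_dataset(anns, preds)
        out = localise_individuals([seq], results)
        return assign_labels_max_conf(out, results)

    def test_highest_confidence_label_wins(self):
        out = self._outcomes([("Hymenoptera", 0.6), ("Diptera", 0.8)])
        assert out[0].assigned_label == "Diptera"
        assert out[0].max_confidence == pytest.approx(0.8)

    def test_fine_label_collapses_after_selection(self):
        out = self._outcomes([("Coleoptera", 0.4)])
        assert out[0].assigned_taxon == "Coleoptera"
        assert out[0].assigned_label == "OtherT"

    def test_equal_confidence_tie_earliest_frame(self):
        out = self._outcomes([("Diptera", 0.5), ("Hymenoptera", 0.5)])
        assert out[0].assigned_label == "Diptera"

    def test_unlocalised_gets_no_label(self):
        seq, anns = _sequence(2)
        results = match_dataset(anns, [])
        out = assign_labels_max_conf(localise_individuals([seq], results), results)
        assert out[0].assigned_label is None and out[0].max_confidence is None


class TestConfusionMatrix:
    def test_rows_sum_to_group_sizes(self):
        seqs, results = [], []
        for i, (taxon, label) in enumerate(
            [("Hymenoptera", "Hymenoptera"), ("Hymenoptera", "Diptera"), ("Diptera", None)]
        ):
            seq, anns = _sequence(2, taxon=taxon, individual_id=f"A{i}", session_id=f"S{i}")
            preds = (
                [make_pred(0, 0, 10, 10, image_id=anns[0].image_id, label=label, confidence=0.5)]
                if label
                else []
            )
            seqs.append(seq)
            results.extend(match_dataset(anns, preds))
        out = assign_labels_max_conf(localise_individuals(seqs, results), results)
        cm = confusion_matrix(out)
        assert cm.loc["Hymenoptera"].sum() == 2
        assert cm.loc["Diptera", BACKGROUND] == 1
        assert cm.to_numpy().sum() == 3

    def test_all_unlocalised_mass_in_background(self):
        seqs = []
        for i, g in enumerate(["Hymenoptera", "Diptera", "OtherT"]):
            seq, _ = _sequence(1, taxon="Coleoptera" if g == "OtherT" else g,
                               individual_id=f"A{i}", session_id=f"S{i}")
            seqs.append(seq)
        cm = confusion_matrix(localise_individuals(seqs, []))
        assert cm[BACKGROUND].sum() == 3
        assert cm.drop(columns=BACKGROUND).to_numpy().sum() == 0

    def test_percentage_view(self):
        cm = confusion_from_counts(
            {"Hymenoptera": [8, 2, 0, 0], "Diptera": [0, 5, 0, 5], "OtherT": [0, 0, 0, 10]}
        )
        pct = confusion_percentages(cm)
        assert pct.loc["Hymenoptera", "Hymenoptera"] == pytest.approx(80.0)
        assert pct.sum(axis=1).to_numpy() == pytest.approx([100.0] * 3)


TABLE_COUNTS = {
    "Hymenoptera": [815, 86, 23, 89],
    "Diptera": [11, 97, 9, 28],
    "OtherT": [8, 2, 59, 54],
}


class TestMetrics:
    def test_per_class_metrics_reconcile_study_table(self):
        """The printed per-class confusion counts reproduce every printed
        P/R/F1/accuracy and localisation rate at 4 decimals."""
        cm = confusion_from_counts(TABLE_COUNTS)
        m = class_metrics(cm)
        expected = {
            "Hymenoptera": (0.9121, 0.9772, 0.8045, 0.8825, 0.8306),
            "Diptera": (0.8069, 0.5243, 0.6690, 0.5879, 0.8938),
            "OtherT": (0.5610, 0.6484, 0.4797, 0.5514, 0.9251),
        }
        for cls, (loc, p, r, f1, acc) in expected.items():
            row = m.loc[cls]
            assert row["localisation_recall"] == pytest.approx(loc, abs=1e-4)
            assert row["precision"] == pytest.approx(p, abs=1e-4)
            assert row["recall"] == pytest.approx(r, abs=1e-4)
            assert row["f1"] == pytest.approx(f1, abs=1e-4)
            assert row["accuracy"] == pytest.approx(acc, abs=1e-4)

    def test_overall_row_reconciles_study_table(self):
        cm = confusion_from_counts(TABLE_COUNTS)
        o = overall_metrics(cm)
        assert o["n_individuals"] == 1281 and o["n_localised"] == 1110
        assert o["localisation_recall"] == pytest.approx(0.8665, abs=1e-4)
        assert o["precision"] == pytest.approx(0.8944, abs=1e-4)
        assert o["recall"] == pytest.approx(0.7580, abs=1e-4)
        assert o["f1"] == pytest.approx(0.8205, abs=1e-4)
        assert o["accuracy"] == pytest.approx(0.8468, abs=1e-4)

    def test_degenerate_single_class_perfect(self):
        cm = confusion_from_counts({"Hymenoptera": [10, 0, 0, 0], "Diptera": [0, 0, 0, 0], "OtherT": [0, 0, 0, 0]})
        row = class_metrics(cm).loc["Hymenoptera"]
        assert row["precision"] == 1.0 and row["recall"] == 1.0 and row["accuracy"] == 1.0

    def test_never_predicted_class_has_nan_precision(self):
        cm = confusion_from_counts({"Hymenoptera": [5, 0, 0, 0], "Diptera": [0, 0, 0, 2], "OtherT": [0, 0, 0, 0]})
        assert np.isnan(class_metrics(cm).loc["Diptera", "precision"])

    def test_single_class_overall_equals_class_row(self):
        cm = confusion_from_counts({"Hymenoptera": [9, 1, 0, 2], "Diptera": [0, 0, 0, 0], "OtherT": [0, 0, 0, 0]})
        row = class_metrics(cm).loc["Hymenoptera"]
        o = overall_metrics(cm)
        assert o["recall"] == pytest.approx(row["recall"])
        assert o["localisation_recall"] == pytest.approx(row["localisation_recall"])

    def test_two_equal_classes_weighted_precision(self):
        # class A predicted perfectly, class B always wrong -> overall P 0.5
        cm = confusion_from_counts({"Hymenoptera": [10, 0, 0, 0], "Diptera": [10, 0, 0, 0], "OtherT": [0, 0, 0, 0]})
        # P(Hym) = 10/20 = 0.5, P(Dip) undefined; use a clean two-class case:
        cm = confusion_from_counts({"Hymenoptera": [10, 0, 0, 0], "Diptera": [0, 0, 10, 0], "OtherT": [0, 0, 0, 0]})
        m = class_metrics(cm)
        assert m.loc["Hymenoptera", "precision"] == 1.0
        assert m.loc["Diptera", "recall"] == 0.0

    def test_metrics_table_layout(self):
        table = metrics_table(confusion_from_counts(TABLE_COUNTS))
        assert list(table.index) == ["Hymenoptera", "Diptera", "OtherT", "Overall"]
        assert table.loc["Overall", "n_individuals"] == 1281
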