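"""Annotation parsing, dataset construction and summaries."""

import json

import pytest

from pollieval.annotations import (
    Box,
    FilterRules,
    ViaKeyMap,
    assemble_individuals,
    crop_to_roi,
    filter_dataset,
    parse_via_annotations,
    read_annotations_csv,
    summarize_dataset,
    write_annotations_csv,
    write_via_csv,
)

from conftest import make_gt


def _via_csv_row(filename, shape, attrs, region_count=1, region_id=0):
    return (
        f'{filename},-1,"{{}}",{region_count},{region_id},'
        f'"{json.dumps(shape).replace(chr(34), chr(34) * 2)}",'
        f'"{json.dumps(attrs).replace(chr(34), chr(34) * 2)}"'
    )


VIA_HEADER = "filename,file_size,file_attributes,region_count,region_id,region_shape_attributes,region_attributes"


class TestBox:
    def test_properties(self):
        b = Box(10, 20, 30, 40)
        assert (b.x_max, b.y_max, b.area) == (40, 60, 1200)

    @pytest.mark.parametrize("bad", [(-1, 0, 5, 5), (0, 0, 0, 5), (0, 0, 5, -2), (float("nan"), 0, 5, 5)])
    def test_invalid_boxes_rejected(self, bad):
        with pytest.raises(ValueError):
            Box(*bad)


class TestViaParsing:
    def test_rect_region_maps_fields(self, tmp_path):
        f = tmp_path / "via.csv"
        f.write_text(
            VIA_HEADER
            + "\n"
            + _via_csv_row(
                "sess1_000007.jpg",
                {"name": "rect", "x": 10, "y": 20, "width": 30, "height": 40},
                {"taxon": "Diptera", "id": "D1"},
            )
            + "\n"
        )
        anns = parse_via_annotations(f)
        assert len(anns) == 1
        a = anns[0]
        assert (a.box.x_min, a.box.y_min, a.box.width, a.box.height) == (10, 20, 30, 40)
        assert a.taxon == "Diptera" and a.individual_id == "D1"
        assert a.session_id == "sess1" and a.frame_index == 7
        assert not a.is_roi

    def test_roi_plus_arthropod(self, tmp_path):
        f = tmp_path / "via.csv"
        rows = [
            _via_csv_row("s_000001.jpg", {"name": "rect", "x": 0, "y": 0, "width": 100, "height": 100}, {"roi": "1"}, 2, 0),
            _via_csv_row("s_000001.jpg", {"name": "rect", "x": 5, "y": 5, "width": 10, "height": 10}, {"taxon": "Hymenoptera", "id": "A"}, 2, 1),
        ]
        f.write_text(VIA_HEADER + "\n" + "\n".join(rows) + "\n")
        anns = parse_via_annotations(f)
        assert len(anns) == 2
        assert sum(a.is_roi for a in anns) == 1

    def test_non_rect_shape_names_row(self, tmp_path):
        f = tmp_path / "via.csv"
        f.write_text(
            VIA_HEADER
            + "\n"
            + _via_csv_row("s_000001.jpg", {"name": "circle", "cx": 5, "cy": 5, "r": 3}, {"taxon": "Diptera", "id": "D1"})
            + "\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            parse_via_annotations(f)

    def test_region_without_taxon_or_roi_rejected(self, tmp_path):
        f = tmp_path / "via.csv"
        f.write_text(
            VIA_HEADER
            + "\n"
            + _via_csv_row("s_000001.jpg", {"name": "rect", "x": 0, "y": 0, "width": 5, "height": 5}, {})
            + "\n"
        )
        with pytest.raises(ValueError, match="neither"):
            parse_via_annotations(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_via_annotations(tmp_path / "nope.csv")

    def test_json_project_dialect(self, tmp_path):
        f = tmp_path / "proj.json"
        project = {
            "_via_img_metadata": {
                "s_000003.jpg-1": {
                    "filename": "s_000003.jpg",
                    "regions": [
                        {
                            "shape_attributes": {"name": "rect", "x": 1, "y": 2, "width": 3, "height": 4},
                            "region_attributes": {"taxon": "Coleoptera", "id": "C9"},
                        }
                    ],
                }
            }
        }
        f.write_text(json.dumps(project))
        anns = parse_via_annotations(f, dialect="json")
        assert len(anns) == 1 and anns[0].taxon == "Coleoptera" and anns[0].frame_index == 3

    def test_custom_attribute_keys(self, tmp_path):
        f = tmp_path / "via.csv"
        f.write_text(
            VIA_HEADER
            + "\n"
            + _via_csv_row("s_000001.jpg", {"name": "rect", "x": 0, "y": 0, "width": 5, "height": 5}, {"order": "Diptera", "track": "T1"})
            + "\n"
        )
        anns = parse_via_annotations(f, keys=ViaKeyMap(taxon="order", individual_id="track"))
        assert anns[0].taxon == "Diptera" and anns[0].individual_id == "T1"


class TestRoundTrips:
    def _sample(self):
        return [
            make_gt(0, 0, 100, 100, is_roi=True, taxon="", individual_id=""),
            make_gt(10, 10, 20, 20, taxon="Hymenoptera", individual_id="A"),
            make_gt(40, 40, 8, 12, image_id="S0_000002.jpg", frame_index=2, taxon="Diptera", individual_id="B", co_occurring=True),
        ]

    def test_via_csv_round_trip(self, tmp_path):
        anns = self._sample()
        f = tmp_path / "via.csv"
        write_via_csv(anns, f)
        assert parse_via_annotations(f) == anns

    def test_canonical_csv_round_trip(self, tmp_path):
        anns = self._sample()
        f = tmp_path / "canonical.csv"
        write_annotations_csv(anns, f)
        assert read_annotations_csv(f) == anns


class TestCropToRoi:
    def test_arthropod_inside_roi(self):
        anns = [make_gt(0, 0, 100, 100, is_roi=True), make_gt(10, 10, 20, 20)]
        crop, shifted = crop_to_roi(anns)
        assert (crop.x_min, crop.y_min, crop.width, crop.height) == (0, 0, 100, 100)
        assert shifted[1].box == anns[1].box

    def test_arthropod_at_edge_extends_crop(self):
        anns = [make_gt(0, 0, 100, 100, is_roi=True), make_gt(90, 90, 20, 20)]
        crop, _ = crop_to_roi(anns)
        assert (crop.width, crop.height) == (110, 110)

    def test_offset_roi_shifts_coordinates(self):
        anns = [make_gt(50, 60, 100, 100, is_roi=True), make_gt(70, 80, 10, 10)]
        crop, shifted = crop_to_roi(anns)
        assert (crop.x_min, crop.y_min) == (50, 60)
        assert (shifted[1].box.x_min, shifted[1].box.y_min) == (20, 20)

    def test_requires_one_roi_and_one_arthropod(self):
        with pytest.raises(ValueError):
            crop_to_roi([make_gt(0, 0, 100, 100, is_roi=True)])
        with pytest.raises(ValueError):
            crop_to_roi([make_gt(10, 10, 20, 20)])
        with pytest.raises(ValueError):
            crop_to_roi(
                [make_gt(0, 0, 50, 50, is_roi=True), make_gt(0, 0, 90, 90, is_roi=True), make_gt(1, 1, 5, 5)]
            )

    def test_idempotent_and_in_bounds(self, rng):
        for _ in range(50):
            roi = make_gt(rng.uniform(0, 50), rng.uniform(0, 50), rng.uniform(20, 80), rng.uniform(20, 80), is_roi=True)
            arts = [
                make_gt(rng.uniform(0, 120), rng.uniform(0, 120), rng.uniform(2, 30), rng.uniform(2, 30), individual_id=f"i{k}")
                for k in range(rng.integers(1, 4))
            ]
            crop1, shifted1 = crop_to_roi([roi] + arts)
            crop2, shifted2 = crop_to_roi(shifted1)
            # second application leaves sizes and every coordinate unchanged
            assert (crop2.width, crop2.height) == pytest.approx((crop1.width, crop1.height))
            assert (crop2.x_min, crop2.y_min) == (0, 0)
            assert [a.box for a in shifted2] == [a.box for a in shifted1]
            for a in shifted1:
                assert a.box.x_min >= 0 and a.box.y_min >= 0
                assert a.box.x_max <= crop1.width + 1e-9
                assert a.box.y_max <= crop1.height + 1e-9


class TestFilterDataset:
    def test_rule_application(self):
        anns = [
            make_gt(0, 0, 5, 5, taxon="Diptera", individual_id="a"),
            make_gt(0, 0, 5, 5, taxon="Thysanoptera", individual_id="b"),
            make_gt(0, 0, 5, 5, taxon="unknown", individual_id="c"),
        ]
        kept, log = filter_dataset(anns)
        assert [a.taxon for a in kept] == ["Diptera"]
        assert (log.excluded_taxon, log.unknown_taxon, log.co_occurring) == (1, 1, 0)

    def test_identity_when_nothing_matches(self):
        anns = [make_gt(0, 0, 5, 5, taxon="Diptera", individual_id=str(i)) for i in range(5)]
        kept, log = filter_dataset(anns)
        assert kept == anns and log.total_removed == 0

    def test_co_occurring_count(self):
        anns = [
            make_gt(0, 0, 5, 5, taxon="Diptera", individual_id=str(i), co_occurring=i < 10)
            for i in range(100)
        ]
        kept, log = filter_dataset(anns)
        assert len(kept) == 90 and log.co_occurring == 10

    def test_retain_unknown_flag(self):
        anns = [make_gt(0, 0, 5, 5, taxon="unknown", individual_id="u")]
        kept, _ = filter_dataset(anns, FilterRules(drop_unknown=False))
        assert len(kept) == 1


class TestAssembleIndividuals:
    def test_consecutive_frames_one_sequence(self):
        anns = [make_gt(0, 0, 5, 5, image_id=f"S0_{i:06d}.jpg", frame_index=i) for i in (1, 2, 3)]
        seqs = assemble_individuals(anns)
        assert len(seqs) == 1 and len(seqs[0]) == 3
        assert seqs[0].group == "Hymenoptera"

    def test_occlusion_gap_keeps_one_sequence(self):
        anns = [make_gt(0, 0, 5, 5, image_id=f"S0_{i:06d}.jpg", frame_index=i) for i in (1, 2, 5, 6)]
        seqs = assemble_individuals(anns)
        assert len(seqs) == 1 and len(seqs[0]) == 4
        assert [a.frame_index for a in seqs[0].annotations] == [1, 2, 5, 6]

    def test_two_ids_same_frame_two_sequences(self):
        anns = [
            make_gt(0, 0, 5, 5, individual_id="A"),
            make_gt(20, 20, 5, 5, individual_id="B", taxon="Hymenoptera-Formicidae"),
        ]
        seqs = assemble_individuals(anns)
        assert len(seqs) == 2
        assert {s.group for s in seqs} == {"Hymenoptera", "OtherT"}

    def test_id_reused_across_sessions_is_distinct_and_warned(self):
        anns = [
            make_gt(0, 0, 5, 5, session_id="S0"),
            make_gt(0, 0, 5, 5, session_id="S1", image_id="S1_000001.jpg"),
        ]
        with pytest.warns(UserWarning, match="distinct"):
            seqs = assemble_individuals(anns)
        assert len(seqs) == 2

    def test_missing_individual_id_raises(self):
        with pytest.raises(ValueError, match="individual_id"):
            assemble_individuals([make_gt(0, 0, 5, 5, individual_id="")])


class TestSummarizeDataset:
    def test_image_percentage_at_study_scale(self):
        # one category spanning 13,084 of 23,899 images -> 54.75%
        anns = [
            make_gt(0, 0, 5, 5, image_id=f"S0_{i:06d}.jpg", frame_index=i)
            for i in range(13084)
        ]
        seqs = assemble_individuals(anns)
        summary = summarize_dataset(seqs, n_images_total=23899)
        assert summary.per_category["pct_images"].iloc[0] == pytest.approx(54.75, abs=0.005)

    def test_median_visit_duration(self):
        anns = [make_gt(0, 0, 5, 5, image_id=f"S0_{i:06d}.jpg", frame_index=i) for i in range(7)]
        seqs = assemble_individuals(anns)
        summary = summarize_dataset(seqs, n_images_total=7, frame_interval_s=1.6)
        assert summary.median_boxes_per_individual == 7
        assert summary.median_visit_duration_s == pytest.approx(11.2)

    def test_single_group_percentages(self):
        anns = [make_gt(0, 0, 5, 5)]
        seqs = assemble_individuals(anns)
        summary = summarize_dataset(seqs, n_images_total=1)
        row = summary.per_category.iloc[0]
        assert row["pct_individuals"] == 100 and row["cumulative_pct"] == 100

    def test_cumulative_and_totals(self):
        anns = [
            make_gt(0, 0, 5, 5, individual_id="A", taxon="Hymenoptera"),
            make_gt(0, 0, 5, 5, individual_id="B", taxon="Diptera", image_id="S0_000002.jpg", frame_index=2),
            make_gt(0, 0, 5, 5, individual_id="C", taxon="Diptera", image_id="S0_000003.jpg", frame_index=3),
        ]
        seqs = assemble_individuals(anns)
        summary = summarize_dataset(seqs, n_images_total=3)
        df = summary.per_category
        assert df["n_individuals"].sum() == len(seqs)
        assert df["cumulative_pct"].iloc[-1] == pytest.approx(100, abs=0.01)
        assert df["cumulative_pct"].is_monotonic_increasing

    def test_relative_area_column_with_image_sizes(self):
        anns = [make_gt(0, 0, 10, 10)]
        seqs = assemble_individuals(anns)
        sizes = {"S0_000001.jpg": (100, 100)}
        summary = summarize_dataset(seqs, n_images_total=1, image_sizes=sizes)
        assert summary.per_category["mean_rel_box_area"].iloc[0] == pytest.approx(0.01)
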