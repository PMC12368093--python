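"""Ground-truth annotations and detector predictions for time-lapse datasets.

Time-lapse monitoring of flower visits produces, per recording session, an
ordered sequence of frames; a human annotator marks every visiting arthropod
with an axis-aligned bounding box, a taxon label (taxonomic order) and an
individual identifier that persists across consecutive frames (and across
short occlusions by flower parts).  Each annotated frame additionally carries
exactly one region-of-interest (ROI) box around the target flower.

This module reads VGG Image Annotator (VIA) exports and a flat "canonical"
CSV, applies the dataset-construction steps (ROI-guided cropping, taxon
filtering, removal of co-occurring non-interacting boxes), groups boxes into
per-individual sequences, and summarises the dataset.
"""

from __future__ import annotations

import csv
import json
import math
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Box",
    "GroundTruthAnnotation",
    "Prediction",
    "IndividualSequence",
    "DatasetSummary",
    "FilterRules",
    "FilterLog",
    "ViaKeyMap",
    "DEFAULT_GROUPING",
    "GROUPS",
    "TAXA",
    "parse_via_annotations",
    "crop_to_roi",
    "filter_dataset",
    "assemble_individuals",
    "summarize_dataset",
    "read_annotations_csv",
    "write_annotations_csv",
    "write_via_csv",
    "read_predictions_csv",
    "write_predictions_csv",
    "read_yolo_predictions",
]

#: Taxon labels the upstream detector can emit (taxonomic orders, plus the
#: ant family split out of Hymenoptera).
TAXA = (
    "Araneae",
    "Coleoptera",
    "Diptera",
    "Hemiptera",
    "Hymenoptera",
    "Hymenoptera-Formicidae",
    "Lepidoptera",
    "Orthoptera",
)

#: Coarse groups used for individual-level analysis.
GROUPS = ("Hymenoptera", "Diptera", "OtherT")

#: Fine taxon -> coarse group.  Ants (Formicidae) are flower visitors but
#: rarely pollinators, hence pooled into OtherT alongside beetles, spiders
#: and true bugs.
DEFAULT_GROUPING: dict[str, str] = {
    t: ("Hymenoptera" if t == "Hymenoptera" else "Diptera" if t == "Diptera" else "OtherT")
    for t in TAXA
}


def group_of(taxon: str, grouping: Mapping[str, str] | None = None) -> str:
    """Collapse a fine taxon label to one of ``GROUPS``."""
    g = (grouping or DEFAULT_GROUPING).get(taxon)
    return g if g is not None else "OtherT"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, top-left origin, 0-based continuous
    coordinates ``(x_min, y_min, width, height)``; area = width x height."""

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "width", "height"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Box.{name} must be finite, got {v!r}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"Box coordinates must be >= 0, got ({self.x_min}, {self.y_min})")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"Box dimensions must be > 0, got {self.width} x {self.height}")

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dx: float, dy: float) -> "Box":
        """Translate by (dx, dy)."""
        return Box(self.x_min + dx, self.y_min + dy, self.width, self.height)


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """One annotated box in one frame.

    ``is_roi`` marks the target-flower region-of-interest box (exactly one
    per annotated image); ``co_occurring`` flags arthropods inside the ROI
    that did not interact with the target flower and are excluded from the
    detector evaluation.
    """

    image_id: str
    session_id: str
    frame_index: int
    box: Box
    taxon: str = ""
    individual_id: str = ""
    is_roi: bool = False
    co_occurring: bool = False


@dataclass(frozen=True)
class Prediction:
    """A detector output: box, class label, confidence in [0, 1]."""

    image_id: str
    box: Box
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class IndividualSequence:
    """All ground-truth boxes of one arthropod individual across one session,
    ordered by frame index (gaps from temporary occlusion are allowed)."""

    individual_id: str
    session_id: str
    taxon: str
    group: str
    annotations: list[GroundTruthAnnotation]

    def __post_init__(self) -> None:
        if not self.annotations:
            raise ValueError("IndividualSequence requires at least one annotation")

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def key(self) -> tuple[str, str]:
        return (self.session_id, self.individual_id)


@dataclass
class DatasetSummary:
    """Per-category dataset summary plus visit-length statistics.

    ``per_category`` columns: taxon, n_boxes, mean_rel_box_area, n_images,
    pct_images, n_individuals, pct_individuals, cumulative_pct.
    """

    per_category: pd.DataFrame
    n_images_total: int
    median_boxes_per_individual: float
    median_visit_duration_s: float


# ---------------------------------------------------------------------------
# VIA parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViaKeyMap:
    """Which VIA region attributes hold each field.

    VIA lets the annotator name attributes freely; these defaults match the
    canonical export of this package and are configurable because upstream
    projects differ.
    """

    taxon: str = "taxon"
    individual_id: str = "id"
    roi: str = "roi"
    co_occurring: str = "co_occurring"


#: Default filename convention: ``<session>_<frame>.<ext>``.
FILENAME_PATTERN = re.compile(r"^(?P<session>.+)_(?P<frame>\d+)\.[A-Za-z]+$")

_TRUTHY = {"1", "true", "yes", "y", "roi"}


def _flag(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUTHY


def _parse_filename(filename: str, pattern: re.Pattern) -> tuple[str, int]:
    m = pattern.match(filename)
    if m:
        return m.group("session"), int(m.group("frame"))
    return Path(filename).stem, 0


def _region_to_annotation(
    filename: str,
    shape: Mapping,
    attrs: Mapping,
    keys: ViaKeyMap,
    pattern: re.Pattern,
    where: str,
) -> GroundTruthAnnotation:
    if shape.get("name") != "rect":
        raise ValueError(f"{where}: unsupported region shape {shape.get('name')!r} (only 'rect')")
    box = Box(float(shape["x"]), float(shape["y"]), float(shape["width"]), float(shape["height"]))
    is_roi = _flag(attrs.get(keys.roi, False))
    taxon = str(attrs.get(keys.taxon, "") or "").strip()
    if not is_roi and not taxon:
        raise ValueError(f"{where}: region has neither a taxon nor an ROI flag")
    session_id, frame_index = _parse_filename(filename, pattern)
    return GroundTruthAnnotation(
        image_id=filename,
        session_id=session_id,
        frame_index=frame_index,
        box=box,
        taxon="" if is_roi else taxon,
        individual_id="" if is_roi else str(attrs.get(keys.individual_id, "") or ""),
        is_roi=is_roi,
        co_occurring=_flag(attrs.get(keys.co_occurring, False)),
    )


def parse_via_annotations(
    path: str | Path,
    dialect: str = "csv",
    keys: ViaKeyMap = ViaKeyMap(),
    filename_pattern: re.Pattern = FILENAME_PATTERN,
) -> list[GroundTruthAnnotation]:
    """Parse a VIA 2.x export (CSV or project JSON) into annotations.

    Rectangular regions only; a malformed region raises with its row (CSV)
    or filename (JSON).  Session id and frame index are recovered from the
    filename via ``filename_pattern`` (groups ``session`` and ``frame``);
    files that do not match get session = stem, frame = 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _parse_via_csv(path, keys, filename_pattern)
    if dialect == "json":
        return _parse_via_json(path, keys, filename_pattern)
    raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'json')")


def _parse_via_csv(path: Path, keys: ViaKeyMap, pattern: re.Pattern) -> list[GroundTruthAnnotation]:
    out: list[GroundTruthAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):  # header is line 1
            where = f"{path.name} row {i}"
            try:
                shape = json.loads(row["region_shape_attributes"] or "{}")
                attrs = json.loads(row["region_attributes"] or "{}")
            except (KeyError, json.JSONDecodeError) as exc:
                raise ValueError(f"{where}: malformed VIA row ({exc})") from exc
            if not shape:  # image entry without regions
                continue
            out.append(_region_to_annotation(row["filename"], shape, attrs, keys, pattern, where))
    return out


def _parse_via_json(path: Path, keys: ViaKeyMap, pattern: re.Pattern) -> list[GroundTruthAnnotation]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if "_via_img_metadata" in data:
        data = data["_via_img_metadata"]
    out: list[GroundTruthAnnotation] = []
    for entry in data.values():
        filename = entry["filename"]
        for j, region in enumerate(entry.get("regions", [])):
            where = f"{path.name} image {filename} region {j}"
            out.append(
                _region_to_annotation(
                    filename,
                    region["shape_attributes"],
                    region.get("region_attributes", {}),
                    keys,
                    pattern,
                    where,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Canonical CSV / VIA export
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = [
    "session_id",
    "image_id",
    "frame_index",
    "x_min",
    "y_min",
    "width",
    "height",
    "taxon",
    "individual_id",
    "is_roi",
    "co_occurring",
]


def write_annotations_csv(annotations: Iterable[GroundTruthAnnotation], path: str | Path) -> None:
    """Write annotations to the canonical flat CSV."""
    rows = [
        {
            "session_id": a.session_id,
            "image_id": a.image_id,
            "frame_index": a.frame_index,
            "x_min": a.box.x_min,
            "y_min": a.box.y_min,
            "width": a.box.width,
            "height": a.box.height,
            "taxon": a.taxon,
            "individual_id": a.individual_id,
            "is_roi": a.is_roi,
            "co_occurring": a.co_occurring,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_CANONICAL_COLUMNS).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> list[GroundTruthAnnotation]:
    """Read the canonical flat CSV back into annotation objects."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"session_id": str, "image_id": str, "taxon": str, "individual_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GroundTruthAnnotation(
                image_id=row.image_id,
                session_id=row.session_id,
                frame_index=int(row.frame_index),
                box=Box(float(row.x_min), float(row.y_min), float(row.width), float(row.height)),
                taxon=row.taxon,
                individual_id=row.individual_id,
                is_roi=_flag(row.is_roi),
                co_occurring=_flag(getattr(row, "co_occurring", False)),
            )
        )
    return out


def write_via_csv(
    annotations: Sequence[GroundTruthAnnotation],
    path: str | Path,
    keys: ViaKeyMap = ViaKeyMap(),
) -> None:
    """Write annotations as a VIA 2.x CSV export.

    The image filename is the annotation's ``image_id``; if that follows the
    ``<session>_<frame>.<ext>`` convention the file round-trips through
    :func:`parse_via_annotations` to an identical annotation list.
    """
    by_image: dict[str, list[GroundTruthAnnotation]] = defaultdict(list)
    for a in annotations:
        by_image[a.image_id].append(a)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "file_size", "file_attributes", "region_count", "region_id", "region_shape_attributes", "region_attributes"]
        )
        for image_id, anns in by_image.items():
            for rid, a in enumerate(anns):
                shape = {
                    "name": "rect",
                    "x": a.box.x_min,
                    "y": a.box.y_min,
                    "width": a.box.width,
                    "height": a.box.height,
                }
                attrs: dict[str, object] = {}
                if a.is_roi:
                    attrs[keys.roi] = "1"
                else:
                    attrs[keys.taxon] = a.taxon
                    attrs[keys.individual_id] = a.individual_id
                    if a.co_occurring:
                        attrs[keys.co_occurring] = "1"
                writer.writerow([image_id, -1, "{}", len(anns), rid, json.dumps(shape), json.dumps(attrs)])


# --- predictions ------------------------------------------------------------

_PRED_COLUMNS = ["image_id", "x_min", "y_min", "width", "height", "label", "confidence"]


def write_predictions_csv(predictions: Iterable[Prediction], path: str | Path) -> None:
    rows = [
        {
            "image_id": p.image_id,
            "x_min": p.box.x_min,
            "y_min": p.box.y_min,
            "width": p.box.width,
            "height": p.box.height,
            "label": p.label,
            "confidence": p.confidence,
        }
        for p in predictions
    ]
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> list[Prediction]:
    df = pd.read_csv(path, keep_default_na=False, dtype={"image_id": str, "label": str})
    return [
        Prediction(
            image_id=row.image_id,
            box=Box(float(row.x_min), float(row.y_min), float(row.width), float(row.height)),
            label=row.label,
            confidence=float(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]


def read_yolo_predictions(
    directory: str | Path,
    image_sizes: Mapping[str, tuple[int, int]],
    class_names: Sequence[str] = TAXA,
    suffix: str = ".txt",
) -> list[Prediction]:
    """Read YOLO-format per-image label files.

    Each ``<image_id>.txt`` holds lines ``class x_center y_center w h [conf]``
    with coordinates normalised to the image size; ``image_sizes`` maps
    image id (file stem) to ``(width, height)`` in pixels.
    """
    out: list[Prediction] = []
    for f in sorted(Path(directory).glob(f"*{suffix}")):
        image_id = f.stem
        if image_id not in image_sizes:
            raise KeyError(f"no image size registered for {image_id!r}")
        w_img, h_img = image_sizes[image_id]
        for ln, line in enumerate(f.read_text().splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (5, 6):
                raise ValueError(f"{f.name} line {ln}: expected 5 or 6 fields, got {len(parts)}")
            cls, xc, yc, w, h = int(parts[0]), *map(float, parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
            box = Box(
                max(0.0, (xc - w / 2) * w_img),
                max(0.0, (yc - h / 2) * h_img),
                w * w_img,
                h * h_img,
            )
            out.append(Prediction(image_id=image_id, box=box, label=class_names[cls], confidence=conf))
    return out


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


def crop_to_roi(
    annotations_of_image: Sequence[GroundTruthAnnotation],
) -> tuple[Box, list[GroundTruthAnnotation]]:
    """ROI-guided crop for one image.

    The crop is the minimal rectangle containing the ROI box *and* every
    arthropod box, so that visitors at the ROI edge are not cut off; all
    boxes are re-expressed relative to the crop origin.  Idempotent: a second
    application leaves every coordinate unchanged (crop at origin).
    """
    rois = [a for a in annotations_of_image if a.is_roi]
    arthropods = [a for a in annotations_of_image if not a.is_roi]
    if len(rois) != 1:
        raise ValueError(f"expected exactly one ROI box, got {len(rois)}")
    if not arthropods:
        raise ValueError("image has an ROI but no arthropod boxes")
    boxes = [a.box for a in annotations_of_image]
    x0 = min(b.x_min for b in boxes)
    y0 = min(b.y_min for b in boxes)
    x1 = max(b.x_max for b in boxes)
    y1 = max(b.y_max for b in boxes)
    crop = Box(x0, y0, x1 - x0, y1 - y0)
    shifted = [replace(a, box=a.box.shifted(-x0, -y0)) for a in annotations_of_image]
    return crop, shifted


@dataclass(frozen=True)
class FilterRules:
    """Which boxes to drop before evaluation."""

    exclude_taxa: frozenset[str] = frozenset({"Thysanoptera"})
    drop_unknown: bool = True  # boxes whose order could not be identified
    drop_co_occurring: bool = True  # in-ROI arthropods not visiting the flower


@dataclass
class FilterLog:
    """Counts of boxes removed per rule."""

    excluded_taxon: int = 0
    unknown_taxon: int = 0
    co_occurring: int = 0

    @property
    def total_removed(self) -> int:
        return self.excluded_taxon + self.unknown_taxon + self.co_occurring


def filter_dataset(
    annotations: Iterable[GroundTruthAnnotation],
    rules: FilterRules = FilterRules(),
) -> tuple[list[GroundTruthAnnotation], FilterLog]:
    """Apply the exclusion rules; ROI boxes are never filtered.

    Returns the retained annotations and a per-rule removal log.
    """
    kept: list[GroundTruthAnnotation] = []
    log = FilterLog()
    for a in annotations:
        if a.is_roi:
            kept.append(a)
            continue
        if a.taxon in rules.exclude_taxa:
            log.excluded_taxon += 1
        elif rules.drop_unknown and a.taxon.lower() in ("", "unknown"):
            log.unknown_taxon += 1
        elif rules.drop_co_occurring and a.co_occurring:
            log.co_occurring += 1
        else:
            kept.append(a)
    return kept, log


def assemble_individuals(
    annotations: Iterable[GroundTruthAnnotation],
    grouping: Mapping[str, str] | None = None,
) -> list[IndividualSequence]:
    """Group arthropod boxes into per-individual sequences.

    One sequence per unique ``(session_id, individual_id)`` pair — an
    identifier reused in two sessions denotes two distinct individuals (a
    warning is emitted).  Frames are ordered; gaps from occlusion stay within
    a single sequence because the annotator kept the identifier.
    """
    by_key: dict[tuple[str, str], list[GroundTruthAnnotation]] = defaultdict(list)
    for a in annotations:
        if a.is_roi:
            continue
        if not a.individual_id:
            raise ValueError(f"arthropod box in image {a.image_id!r} lacks an individual_id")
        by_key[(a.session_id, a.individual_id)].append(a)

    sessions_of_id: dict[str, set[str]] = defaultdict(set)
    for session_id, individual_id in by_key:
        sessions_of_id[individual_id].add(session_id)
    for individual_id, sessions in sessions_of_id.items():
        if len(sessions) > 1:
            warnings.warn(
                f"individual_id {individual_id!r} appears in {len(sessions)} sessions; "
                "treated as distinct individuals per session",
                stacklevel=2,
            )

    out = []
    for (session_id, individual_id), anns in sorted(by_key.items()):
        anns = sorted(anns, key=lambda a: a.frame_index)
        taxon = anns[0].taxon
        out.append(
            IndividualSequence(
                individual_id=individual_id,
                session_id=session_id,
                taxon=taxon,
                group=group_of(taxon, grouping),
                annotations=anns,
            )
        )
    return out


def summarize_dataset(
    sequences: Sequence[IndividualSequence],
    n_images_total: int,
    frame_interval_s: float = 1.6,
    image_sizes: Mapping[str, tuple[float, float]] | None = None,
) -> DatasetSummary:
    """Per-taxon summary: box counts, mean relative box area, image counts
    and percentages, individual counts, percentages and their cumulative sum;
    plus the median boxes-per-individual and the implied median visit
    duration (median boxes x frame interval).

    ``image_sizes`` (image_id -> (width, height) in pixels) enables the mean
    relative-box-area column; without it that column is NaN.  Percentages of
    images use ``n_images_total`` as denominator; categories can share images
    so image counts may sum past the total.
    """
    if n_images_total <= 0:
        raise ValueError("n_images_total must be positive")
    if not sequences:
        raise ValueError("no sequences to summarise")

    rows = []
    by_taxon: dict[str, list[IndividualSequence]] = defaultdict(list)
    for s in sequences:
        by_taxon[s.taxon].append(s)
    n_individuals_total = len(sequences)

    for taxon, seqs in sorted(by_taxon.items(), key=lambda kv: -len(kv[1])):
        anns = [a for s in seqs for a in s.annotations]
        images = {a.image_id for a in anns}
        if image_sizes is not None:
            rel = [a.box.area / (image_sizes[a.image_id][0] * image_sizes[a.image_id][1]) for a in anns]
            mean_rel = sum(rel) / len(rel)
        else:
            mean_rel = float("nan")
        rows.append(
            {
                "taxon": taxon,
                "n_boxes": len(anns),
                "mean_rel_box_area": mean_rel,
                "n_images": len(images),
                "pct_images": 100.0 * len(images) / n_images_total,
                "n_individuals": len(seqs),
                "pct_individuals": 100.0 * len(seqs) / n_individuals_total,
            }
        )
    df = pd.DataFrame(rows)
    df["cumulative_pct"] = df["pct_individuals"].cumsum()

    lengths = sorted(len(s) for s in sequences)
    median_boxes = _median(lengths)
    return DatasetSummary(
        per_category=df,
        n_images_total=n_images_total,
        median_boxes_per_individual=median_boxes,
        median_visit_duration_s=median_boxes * frame_interval_s,
    )


def _median(sorted_values: Sequence[float]) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return (sorted_values[mid - 1] + sorted_values[mid]) / 2.0
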