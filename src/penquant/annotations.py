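"""Data model and I/O for frame-level pig behavior annotations.

A recording is a sequence of frames sampled from overhead pen video. Every
pig visible in a frame (more than half its body unoccluded) carries exactly
one axis-aligned bounding box and one behavior/posture category. Six
annotation categories (standing, three non-standing variants, drinking,
feeding) collapse onto the four detection classes the quantification
pipeline operates on.

Two file dialects are supported and round-trip losslessly:

* a COCO-style JSON dialect (``bbox`` as ``[x, y, w, h]``) with per-image
  ``pen_id``, ``lighting`` and ``timestamp`` fields, and
* a flat CSV dialect storing the corner format
  ``[xmin, ymin, xmax, ymax]`` directly, one row per annotated instance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationError",
    "BBox",
    "AnnotationCategory",
    "DetectionClass",
    "Lighting",
    "AnnotatedInstance",
    "FrameRecord",
    "DatasetManifest",
    "ManifestReport",
    "to_detection_class",
    "read_annotations",
    "write_annotations",
    "build_manifest",
    "validate_manifest",
    "VISIBILITY_THRESHOLD",
]

#: Annotation-protocol rule: a pig is labeled only if more than half of its
#: body is unoccluded.
VISIBILITY_THRESHOLD = 0.5


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid records."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box ``[xmin, ymin, xmax, ymax]`` in continuous pixels.

    Origin is the image top-left corner; x grows rightward, y downward.
    ``(xmin, ymin)`` is the upper-left corner and ``(xmax, ymax)`` the
    lower-right corner. Coordinates are continuous; the area is
    ``(xmax - xmin) * (ymax - ymin)`` with no inclusive-pixel ``+1``.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise AnnotationError(
                f"degenerate box [{self.xmin}, {self.ymin}, {self.xmax}, {self.ymax}]: "
                "requires xmax > xmin and ymax > ymin"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def contains_point(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    def contains_box(self, other: "BBox") -> bool:
        return (
            self.xmin <= other.xmin
            and self.ymin <= other.ymin
            and self.xmax >= other.xmax
            and self.ymax >= other.ymax
        )

    def intersection_area(self, other: "BBox") -> float:
        w = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        h = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h

    def dilate(self, margin: float) -> "BBox":
        return BBox(
            self.xmin - margin, self.ymin - margin, self.xmax + margin, self.ymax + margin
        )

    def as_corner_list(self) -> list[float]:
        return [self.xmin, self.ymin, self.xmax, self.ymax]

    def as_xywh(self) -> list[float]:
        return [self.xmin, self.ymin, self.width, self.height]

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BBox":
        return cls(x, y, x + w, y + h)


class AnnotationCategory(str, Enum):
    """The six annotation-time behavior/posture categories.

    ``drinking`` (snout touching the bowl drinker) and ``feeding`` (whole
    head in the trough) take precedence over posture; the three
    non-standing variants distinguish lateral lying, sternal lying and
    sitting.
    """

    STANDING = "standing"
    LYING_LATERAL = "non_standing_lying_lateral"
    LYING_STERNAL = "non_standing_lying_sternal"
    SITTING = "non_standing_sitting"
    DRINKING = "drinking"
    FEEDING = "feeding"


class DetectionClass(str, Enum):
    """The four classes the detector and all downstream analysis use."""

    STANDING = "standing"
    NON_STANDING = "non_standing"
    FEEDING = "feeding"
    DRINKING = "drinking"


class Lighting(str, Enum):
    RGB = "rgb"
    INFRARED = "infrared"


_CATEGORY_TO_CLASS: Mapping[AnnotationCategory, DetectionClass] = {
    AnnotationCategory.STANDING: DetectionClass.STANDING,
    AnnotationCategory.LYING_LATERAL: DetectionClass.NON_STANDING,
    AnnotationCategory.LYING_STERNAL: DetectionClass.NON_STANDING,
    AnnotationCategory.SITTING: DetectionClass.NON_STANDING,
    AnnotationCategory.DRINKING: DetectionClass.DRINKING,
    AnnotationCategory.FEEDING: DetectionClass.FEEDING,
}


def to_detection_class(category: AnnotationCategory) -> DetectionClass:
    """Collapse an annotation category onto its detection class.

    Total mapping: the three non-standing variants map to ``non_standing``;
    the remaining categories map to themselves.
    """
    return _CATEGORY_TO_CLASS[AnnotationCategory(category)]


@dataclass(frozen=True)
class AnnotatedInstance:
    """One labeled pig: a box, a category, and annotation metadata.

    ``pig_id`` is only available for simulator ground truth (the field
    protocol does not identify individuals). ``visible_fraction`` is the
    unoccluded fraction of the pig; annotation files that omit it default
    to 1.0 since real detections carry no occlusion field.
    """

    box: BBox
    category: AnnotationCategory
    pig_id: int | None = None
    visible_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", AnnotationCategory(self.category))
        if not (0.0 <= self.visible_fraction <= 1.0):
            raise AnnotationError(
                f"visible_fraction {self.visible_fraction} outside [0, 1]"
            )

    @property
    def detection_class(self) -> DetectionClass:
        return to_detection_class(self.category)


@dataclass(frozen=True)
class FrameRecord:
    """All annotated instances of one sampled frame."""

    frame_index: int
    timestamp: float
    lighting: Lighting
    pen_id: str
    instances: tuple[AnnotatedInstance, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise AnnotationError(f"negative frame_index {self.frame_index}")
        object.__setattr__(self, "lighting", Lighting(self.lighting))
        object.__setattr__(self, "instances", tuple(self.instances))
        pig_ids = [i.pig_id for i in self.instances if i.pig_id is not None]
        if len(pig_ids) != len(set(pig_ids)):
            raise AnnotationError(
                f"frame {self.frame_index} (pen {self.pen_id}): duplicate pig_id"
            )


def _check_timestamps(frames: Sequence[FrameRecord]) -> None:
    """Timestamps must strictly increase within each pen's recording."""
    last: dict[str, float] = {}
    for fr in frames:
        if fr.pen_id in last and fr.timestamp <= last[fr.pen_id]:
            raise AnnotationError(
                f"pen {fr.pen_id}: timestamp {fr.timestamp} at frame "
                f"{fr.frame_index} does not increase"
            )
        last[fr.pen_id] = fr.timestamp


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "pen_id",
    "frame_index",
    "timestamp_s",
    "lighting",
    "pig_id",
    "category",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
    "visible_fraction",
]

_CATEGORY_ORDER = list(AnnotationCategory)


def _frames_to_coco(frames: Sequence[FrameRecord]) -> dict:
    cat_id = {c: i + 1 for i, c in enumerate(_CATEGORY_ORDER)}
    images = []
    annotations = []
    ann_id = 1
    for img_id, fr in enumerate(frames, start=1):
        images.append(
            {
                "id": img_id,
                "frame_index": fr.frame_index,
                "timestamp": fr.timestamp,
                "lighting": fr.lighting.value,
                "pen_id": fr.pen_id,
            }
        )
        for inst in fr.instances:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[inst.category],
                    "bbox": inst.box.as_xywh(),
                    "area": inst.box.area,
                    "iscrowd": 0,
                    "pig_id": inst.pig_id,
                    "visible_fraction": inst.visible_fraction,
                }
            )
            ann_id += 1
    categories = [
        {"id": cat_id[c], "name": c.value, "supercategory": to_detection_class(c).value}
        for c in _CATEGORY_ORDER
    ]
    return {"images": images, "annotations": annotations, "categories": categories}


def _coco_to_frames(doc: dict) -> list[FrameRecord]:
    try:
        images = doc["images"]
        annotations = doc["annotations"]
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"not a COCO-style document: missing {exc}") from None
    cat_by_id: dict[int, AnnotationCategory] = {}
    for cat in doc.get("categories", []):
        try:
            cat_by_id[cat["id"]] = AnnotationCategory(cat["name"])
        except ValueError:
            raise AnnotationError(f"unknown category name {cat.get('name')!r}") from None
    by_image: dict[int, list[AnnotatedInstance]] = {img["id"]: [] for img in images}
    for ann in annotations:
        img_id = ann.get("image_id")
        if img_id not in by_image:
            raise AnnotationError(f"annotation {ann.get('id')}: unknown image_id {img_id}")
        try:
            x, y, w, h = ann["bbox"]
            box = BBox.from_xywh(x, y, w, h)
        except (KeyError, ValueError, TypeError) as exc:
            raise AnnotationError(f"annotation {ann.get('id')}: bad bbox ({exc})") from None
        cid = ann.get("category_id")
        if cid not in cat_by_id:
            raise AnnotationError(f"annotation {ann.get('id')}: unknown category_id {cid}")
        by_image[img_id].append(
            AnnotatedInstance(
                box=box,
                category=cat_by_id[cid],
                pig_id=ann.get("pig_id"),
                visible_fraction=ann.get("visible_fraction", 1.0),
            )
        )
    frames = []
    for img in sorted(images, key=lambda im: im["id"]):
        try:
            frames.append(
                FrameRecord(
                    frame_index=img["frame_index"],
                    timestamp=img["timestamp"],
                    lighting=Lighting(img["lighting"]),
                    pen_id=img["pen_id"],
                    instances=tuple(by_image[img["id"]]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"image {img.get('id')}: {exc}") from None
    return frames


def _frames_to_csv_rows(frames: Sequence[FrameRecord]) -> Iterable[list[str]]:
    for fr in frames:
        for inst in fr.instances:
            yield [
                fr.pen_id,
                str(fr.frame_index),
                repr(float(fr.timestamp)),
                fr.lighting.value,
                "" if inst.pig_id is None else str(inst.pig_id),
                inst.category.value,
                repr(float(inst.box.xmin)),
                repr(float(inst.box.ymin)),
                repr(float(inst.box.xmax)),
                repr(float(inst.box.ymax)),
                repr(float(inst.visible_fraction)),
            ]
        if not fr.instances:
            # empty frames are preserved as a row with no instance fields
            yield [
                fr.pen_id,
                str(fr.frame_index),
                repr(float(fr.timestamp)),
                fr.lighting.value,
                "",
                "",
                "",
                "",
                "",
                "",
                "",
            ]


def _csv_rows_to_frames(rows: Iterable[Mapping[str, str]]) -> list[FrameRecord]:
    order: list[tuple[str, int]] = []
    meta: dict[tuple[str, int], tuple[float, str]] = {}
    insts: dict[tuple[str, int], list[AnnotatedInstance]] = {}
    for lineno, row in enumerate(rows, start=2):  # header is line 1
        try:
            key = (row["pen_id"], int(row["frame_index"]))
            ts = float(row["timestamp_s"])
            lighting = row["lighting"]
        except (KeyError, ValueError, TypeError) as exc:
            raise AnnotationError(f"CSV line {lineno}: malformed frame fields ({exc})") from None
        if key not in meta:
            meta[key] = (ts, lighting)
            order.append(key)
            insts[key] = []
        if not row.get("category"):
            continue  # empty-frame placeholder row
        try:
            box = BBox(
                float(row["xmin"]), float(row["ymin"]), float(row["xmax"]), float(row["ymax"])
            )
        except (ValueError, TypeError) as exc:
            raise AnnotationError(f"CSV line {lineno}: bad box ({exc})") from None
        except AnnotationError as exc:
            raise AnnotationError(f"CSV line {lineno}: {exc}") from None
        try:
            vf = row.get("visible_fraction", "")
            insts[key].append(
                AnnotatedInstance(
                    box=box,
                    category=AnnotationCategory(row["category"]),
                    pig_id=int(row["pig_id"]) if row.get("pig_id") else None,
                    visible_fraction=float(vf) if vf else 1.0,
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"CSV line {lineno}: {exc}") from None
    return [
        FrameRecord(
            frame_index=k[1],
            timestamp=meta[k][0],
            lighting=Lighting(meta[k][1]),
            pen_id=k[0],
            instances=tuple(insts[k]),
        )
        for k in order
    ]


def read_annotations(path: str | Path, dialect: str = "flat_csv") -> list[FrameRecord]:
    """Read a frame-annotation file.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"coco_json"`` or ``"flat_csv"``.
    """
    path = Path(path)
    if dialect == "coco_json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: invalid JSON ({exc})") from None
        frames = _coco_to_frames(doc)
    elif dialect == "flat_csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or list(reader.fieldnames) != _CSV_COLUMNS:
                raise AnnotationError(
                    f"{path}: expected header {_CSV_COLUMNS}, got {reader.fieldnames}"
                )
            frames = _csv_rows_to_frames(reader)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_timestamps(frames)
    return frames


def write_annotations(
    frames: Sequence[FrameRecord], path: str | Path, dialect: str = "flat_csv"
) -> None:
    """Write frames to ``path`` so that :func:`read_annotations` round-trips."""
    path = Path(path)
    _check_timestamps(frames)
    if dialect == "coco_json":
        path.write_text(json.dumps(_frames_to_coco(frames), indent=1))
    elif dialect == "flat_csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            writer.writerows(_frames_to_csv_rows(frames))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetManifest:
    """Per-class instance/image counts and the train/test split of a dataset."""

    class_instance_counts: Mapping[DetectionClass, int]
    class_image_counts: Mapping[DetectionClass, int]
    total_images: int
    split: Mapping[str, tuple[int, int]]  # name -> (n_images, n_instances)

    @property
    def total_instances(self) -> int:
        return sum(self.class_instance_counts.values())


@dataclass(frozen=True)
class ManifestReport:
    passed: bool
    total_instances: int
    total_images: int
    split_instances: int
    split_images: int
    violations: tuple[str, ...] = ()


def build_manifest(
    frames: Sequence[FrameRecord],
    split_assignment: Mapping[tuple[str, int], str],
) -> DatasetManifest:
    """Count instances/images per detection class and per split.

    ``split_assignment`` maps ``(pen_id, frame_index)`` to ``"train"`` or
    ``"test"``; every frame must be assigned.
    """
    inst_counts = {c: 0 for c in DetectionClass}
    img_counts = {c: 0 for c in DetectionClass}
    split: dict[str, list[int]] = {}
    for fr in frames:
        key = (fr.pen_id, fr.frame_index)
        if key not in split_assignment:
            raise AnnotationError(f"frame {key} not assigned to a split")
        name = split_assignment[key]
        split.setdefault(name, [0, 0])
        split[name][0] += 1
        split[name][1] += len(fr.instances)
        present = set()
        for inst in fr.instances:
            cls = inst.detection_class
            inst_counts[cls] += 1
            present.add(cls)
        for cls in present:
            img_counts[cls] += 1
    return DatasetManifest(
        class_instance_counts=inst_counts,
        class_image_counts=img_counts,
        total_images=len(frames),
        split={k: tuple(v) for k, v in split.items()},
    )


def validate_manifest(manifest: DatasetManifest) -> ManifestReport:
    """Check a manifest's bookkeeping invariants; violations are reported,
    never raised."""
    violations: list[str] = []
    total_instances = sum(manifest.class_instance_counts.values())
    split_images = sum(n for n, _ in manifest.split.values())
    split_instances = sum(n for _, n in manifest.split.values())
    if manifest.split and split_images != manifest.total_images:
        violations.append(
            f"split image counts sum to {split_images}, expected {manifest.total_images}"
        )
    if manifest.split and split_instances != total_instances:
        violations.append(
            f"split instance counts sum to {split_instances}, "
            f"expected class-count total {total_instances}"
        )
    for cls, n in manifest.class_image_counts.items():
        if n > manifest.total_images:
            violations.append(f"{cls.value}: image count {n} exceeds total {manifest.total_images}")
        if n < 0 or manifest.class_instance_counts.get(cls, 0) < 0:
            violations.append(f"{cls.value}: negative count")
    return ManifestReport(
        passed=not violations,
        total_instances=total_instances,
        total_images=manifest.total_images,
        split_instances=split_instances,
        split_images=split_images,
        violations=tuple(violations),
    )
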