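"""Detector contract, confidence filtering, training-schedule math, and a
classical baseline blob detector for rendered synthetic frames.

No neural network ships here. Trained CNN detectors are external: their
outputs are ingested through the detection exchange formats below and they
satisfy :class:`Detector` — a stateless, frame-synchronous callable, so a
false positive at one frame has no implications for the next. The baseline
blob detector is a desk-scale classical detector for the simulator's
rendered frames: connected bright components become boxes, posture is read
from the component's aspect ratio, and drinking/feeding are assigned by
zone membership.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
from skimage import measure

from .annotations import BBox, DetectionClass
from .geometry import PenGeometry

__all__ = [
    "Detection",
    "Detector",
    "ScheduleParams",
    "filter_by_confidence",
    "warmup_lr",
    "baseline_blob_detector",
    "read_detections",
    "write_detections",
]


@dataclass(frozen=True)
class Detection:
    """A scored class prediction: box, detection class, confidence in [0, 1]."""

    box: BBox
    detection_class: DetectionClass
    confidence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "detection_class", DetectionClass(self.detection_class))
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class Detector(Protocol):
    """Stateless frame-synchronous detector: image in, detections out."""

    name: str

    def __call__(self, image: np.ndarray) -> Sequence[Detection]: ...


@dataclass(frozen=True)
class ScheduleParams:
    """Training-schedule parameters of the detector configuration.

    Only the warm-up ramp is executable here (:func:`warmup_lr`); the
    remaining fields are stored so a configuration file can echo the full
    training recipe.
    """

    base_lr: float = 1e-3
    warmup_iterations: int = 1000
    max_epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.5e-3
    batch_size: int = 64
    mini_batch_size: int = 8
    l2_factor: float = 0.5e-3

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.warmup_iterations < 1:
            raise ValueError("warmup_iterations must be >= 1")


def filter_by_confidence(
    detections: Sequence[Detection], threshold: float = 0.5
) -> list[Detection]:
    """Keep only detections with confidence strictly above ``threshold``.

    The deployment rule: a detection at exactly the threshold is dropped.
    Order is preserved.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [d for d in detections if d.confidence > threshold]


def warmup_lr(params: ScheduleParams, iteration: int) -> float:
    """Quartic warm-up learning-rate ramp.

    For ``iteration < warmup_iterations`` the learning rate is
    ``base_lr * (iteration / warmup_iterations) ** 4``; from the warm-up
    boundary on it is the constant ``base_lr``.
    """
    if iteration < 0:
        raise ValueError(f"negative iteration {iteration}")
    if iteration >= params.warmup_iterations:
        return params.base_lr
    return params.base_lr * (iteration / params.warmup_iterations) ** 4


# ---------------------------------------------------------------------------
# baseline blob detector
# ---------------------------------------------------------------------------

#: Pixel intensity separating rendered pigs from floor/zone markings.
_FOREGROUND_THRESHOLD = 150.0

#: Box aspect (long side / short side) at and above which a component is
#: called standing; lying/sitting pigs render wider and squatter.
_STANDING_ASPECT = 1.8


def baseline_blob_detector(
    image: np.ndarray,
    geometry: PenGeometry,
    *,
    min_area: float = 300.0,
    aspect_threshold: float = _STANDING_ASPECT,
    confidence_area: float = 800.0,
) -> list[Detection]:
    """Detect rendered pigs by connected-component analysis.

    Classification: a component whose box center lies inside a drinker
    (feeder) zone is drinking (feeding); otherwise the box aspect ratio
    decides standing vs. non-standing. Confidence is the deterministic
    saturating function ``area / (area + confidence_area)`` of the
    component's pixel area, so larger (less occluded) blobs score higher.
    """
    gray = image.astype(float) if image.ndim == 2 else image.astype(float).mean(axis=2)
    mask = gray > _FOREGROUND_THRESHOLD
    labels = measure.label(mask)
    detections: list[Detection] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        minr, minc, maxr, maxc = region.bbox
        box = BBox(float(minc), float(minr), float(maxc), float(maxr))
        cx, cy = box.center
        if any(z.contains_point(cx, cy) for z in geometry.drinker_zones):
            cls = DetectionClass.DRINKING
        elif any(z.contains_point(cx, cy) for z in geometry.feeder_zones):
            cls = DetectionClass.FEEDING
        else:
            aspect = max(box.width, box.height) / min(box.width, box.height)
            cls = DetectionClass.STANDING if aspect >= aspect_threshold else DetectionClass.NON_STANDING
        conf = region.area / (region.area + confidence_area)
        detections.append(Detection(box=box, detection_class=cls, confidence=conf))
    return detections


# ---------------------------------------------------------------------------
# detection exchange formats
# ---------------------------------------------------------------------------


def write_detections(
    detections: Mapping[int, Sequence[Detection]], path: str | Path, dialect: str = "json"
) -> None:
    """Write per-frame detections.

    ``json``: array of ``{frame_index, class, bbox, confidence}`` objects.
    ``csv``: the same fields flat, mirroring the annotation CSV dialect.
    """
    path = Path(path)
    rows = [
        {
            "frame_index": int(fi),
            "class": d.detection_class.value,
            "bbox": d.box.as_corner_list(),
            "confidence": float(d.confidence),
        }
        for fi in sorted(detections)
        for d in detections[fi]
    ]
    if dialect == "json":
        path.write_text(json.dumps(rows, indent=1))
    elif dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "class", "xmin", "ymin", "xmax", "ymax", "confidence"])
            for r in rows:
                writer.writerow(
                    [r["frame_index"], r["class"], *map(repr, r["bbox"]), repr(r["confidence"])]
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_detections(path: str | Path, dialect: str = "json") -> dict[int, list[Detection]]:
    path = Path(path)
    out: dict[int, list[Detection]] = {}
    if dialect == "json":
        for rec in json.loads(path.read_text()):
            det = Detection(
                box=BBox(*rec["bbox"]),
                detection_class=DetectionClass(rec["class"]),
                confidence=rec["confidence"],
            )
            out.setdefault(int(rec["frame_index"]), []).append(det)
    elif dialect == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                det = Detection(
                    box=BBox(
                        float(rec["xmin"]), float(rec["ymin"]),
                        float(rec["xmax"]), float(rec["ymax"]),
                    ),
                    detection_class=DetectionClass(rec["class"]),
                    confidence=float(rec["confidence"]),
                )
                out.setdefault(int(rec["frame_index"]), []).append(det)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return out
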