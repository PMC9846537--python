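"""Spatial penalization of feeding/drinking detections.

A pig can hold a drinking-like or feeding-like posture anywhere in the
pen, so a detector occasionally emits drinking/feeding boxes far from the
actual water or feed source. This stage uses prior knowledge of the pen
geometry to suppress them: a drinking (feeding) detection that fails a
spatial rule with respect to every — margin-dilated — drinker (feeder)
zone is dropped, or optionally reclassified to a posture class. Posture
detections (standing/non-standing) always pass through unchanged.

The vicinity rule is configurable because no single definition is
canonical: ``center_in_zone`` (default; robust to box-size jitter) tests
the box center, ``box_overlap_fraction`` requires a fraction tau of the
box area inside a zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotations import BBox, DetectionClass
from .detection import Detection
from .geometry import PenGeometry

__all__ = ["PenalizerConfig", "PenalizerError", "penalize", "penalization_report"]

_ZONE_CLASSES = (DetectionClass.DRINKING, DetectionClass.FEEDING)


class PenalizerError(ValueError):
    """Raised for inconsistent penalizer configuration."""


@dataclass(frozen=True)
class PenalizerConfig:
    """Penalization parameters.

    ``margin`` dilates each zone before testing (default half a pig length,
    allowing a box centered just outside the drawn zone while the snout is
    at the source). ``action`` is ``"drop"`` (default — false positives are
    removed, matching an analysis that counts behaviors) or
    ``"reclassify_to_posture"`` (a penalized pig still has some posture).
    """

    margin: float = 50.0
    rule: str = "center_in_zone"
    overlap_fraction: float = 0.5
    action: str = "drop"
    reclassify_to: DetectionClass = DetectionClass.STANDING

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise PenalizerError("margin must be >= 0")
        if self.rule not in ("center_in_zone", "box_overlap_fraction"):
            raise PenalizerError(f"unknown rule {self.rule!r}")
        if self.rule == "box_overlap_fraction" and not (0.0 < self.overlap_fraction <= 1.0):
            raise PenalizerError("overlap_fraction must lie in (0, 1]")
        if self.action not in ("drop", "reclassify_to_posture"):
            raise PenalizerError(f"unknown action {self.action!r}")
        if self.action == "reclassify_to_posture" and self.reclassify_to in _ZONE_CLASSES:
            raise PenalizerError("reclassify_to must be a posture class")


def _passes(box: BBox, zones: Sequence[BBox], config: PenalizerConfig) -> bool:
    dilated = [z.dilate(config.margin) for z in zones]
    if config.rule == "center_in_zone":
        cx, cy = box.center
        return any(z.contains_point(cx, cy) for z in dilated)
    return any(z.intersection_area(box) / box.area >= config.overlap_fraction for z in dilated)


def penalize(
    detections: Sequence[Detection],
    geometry: PenGeometry,
    config: PenalizerConfig | None = None,
) -> list[Detection]:
    """Suppress feeding/drinking detections away from their source.

    Order is preserved; posture detections are untouched. With the
    ``drop`` action the output is a subsequence of the input. Raises
    :class:`PenalizerError` if a behavior present in the detections has no
    configured zone (per-pen geometry is mandatory — sources sit at
    different locations in every pen).
    """
    config = config or PenalizerConfig()
    zone_map: Mapping[DetectionClass, Sequence[BBox]] = {
        DetectionClass.DRINKING: geometry.drinker_zones,
        DetectionClass.FEEDING: geometry.feeder_zones,
    }
    out: list[Detection] = []
    for det in detections:
        if det.detection_class not in _ZONE_CLASSES:
            out.append(det)
            continue
        zones = zone_map[det.detection_class]
        if not zones:
            raise PenalizerError(
                f"no {det.detection_class.value} zone configured but "
                f"{det.detection_class.value} detections are present"
            )
        if _passes(det.box, zones, config):
            out.append(det)
        elif config.action == "reclassify_to_posture":
            out.append(
                Detection(
                    box=det.box,
                    detection_class=config.reclassify_to,
                    confidence=det.confidence,
                )
            )
    return out


def penalization_report(
    before: Sequence[Detection], after: Sequence[Detection]
) -> dict[DetectionClass, dict[str, int]]:
    """Per-class removed/retained counts of a (drop-action) penalization.

    ``removed + retained`` equals the input count for every class; posture
    classes always report zero removals. Counts are derived from the class
    tallies of the two lists, which is exact for the ``drop`` action.
    """
    n_before = {c: 0 for c in DetectionClass}
    n_after = {c: 0 for c in DetectionClass}
    for d in before:
        n_before[d.detection_class] += 1
    for d in after:
        n_after[d.detection_class] += 1
    return {
        c: {"retained": n_after[c], "removed": n_before[c] - n_after[c]}
        for c in DetectionClass
    }
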