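"""Pen geometry: the pen rectangle plus feeder and drinker zones.

Zones are axis-aligned rectangles in the same pixel frame as the
annotations. They drive both the simulator (drinking/feeding pigs are
placed at their source) and the penalizing post-processing stage
(feeding/drinking detections away from the corresponding source are
suppressed). Geometry is per pen: drinker and feeder locations differ
between pens, so there is no global default zone at analysis time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .annotations import BBox

__all__ = ["PenGeometry", "GeometryError", "default_geometry"]


class GeometryError(ValueError):
    """Raised for inconsistent pen geometry."""


@dataclass(frozen=True)
class PenGeometry:
    """Pen extent and resource zones, all in pixels.

    The single bowl drinker of a typical nursery pen is the default
    (one drinker zone); the dry multi-space feeder may be described by one
    or several feeder zones.
    """

    pen: BBox
    feeder_zones: tuple[BBox, ...]
    drinker_zones: tuple[BBox, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "feeder_zones", tuple(self.feeder_zones))
        object.__setattr__(self, "drinker_zones", tuple(self.drinker_zones))
        for name, zones in (("feeder", self.feeder_zones), ("drinker", self.drinker_zones)):
            for z in zones:
                if not self.pen.contains_box(z):
                    raise GeometryError(f"{name} zone {z.as_corner_list()} outside pen")
        for f in self.feeder_zones:
            for d in self.drinker_zones:
                if f.intersection_area(d) > 0:
                    raise GeometryError(
                        f"feeder zone {f.as_corner_list()} overlaps drinker zone "
                        f"{d.as_corner_list()}"
                    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "pen": self.pen.as_corner_list(),
            "feeder_zones": [z.as_corner_list() for z in self.feeder_zones],
            "drinker_zones": [z.as_corner_list() for z in self.drinker_zones],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PenGeometry":
        return cls(
            pen=BBox(*d["pen"]),
            feeder_zones=tuple(BBox(*z) for z in d.get("feeder_zones", [])),
            drinker_zones=tuple(BBox(*z) for z in d.get("drinker_zones", [])),
        )

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "PenGeometry":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def default_geometry() -> PenGeometry:
    """A 2.7 m x 1.4 m nursery pen at ~200 px/m.

    The multi-space feeder is a strip along the top wall; the single bowl
    drinker sits near the opposite corner. Zone sizes are generous enough
    that a pig box centered in the zone stays inside the pen.
    """
    pen = BBox(20.0, 20.0, 560.0, 300.0)
    feeder = BBox(140.0, 20.0, 440.0, 70.0)
    drinker = BBox(480.0, 230.0, 560.0, 300.0)
    return PenGeometry(pen=pen, feeder_zones=(feeder,), drinker_zones=(drinker,))
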