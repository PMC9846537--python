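"""Agent-based synthetic generator of pen recordings.

Each pig is an independent discrete-time Markov chain over the six
annotation categories, stepped at the frame-sampling cadence (default one
frame every 20 s, i.e. 0.05 frame/s — at that spacing frame-to-frame
spatial correlation is unnecessary and pig positions are re-sampled
uniformly each frame). Behaviors are tied to pen geometry: a drinking pig
is placed with its box center inside a drinker zone and a feeding pig
inside a feeder zone. The single bowl drinker admits one pig at a time
(so at most one drinking instance per frame, matching a one-drinker pen);
the multi-space feeder admits ``feeder_spaces`` pigs. A pig whose chain
proposes an occupied resource stays in its previous state.

Occlusion follows the annotation protocol: pigs placed later lie on top,
``visible_fraction`` is the unoccluded area fraction of each box, and
instances below the visibility threshold (default 0.5) are dropped from
the ground truth.

A detection-noise model (:func:`perturb_to_detections`) turns ground truth
into detector-like output — localization jitter, misses, Poisson spurious
boxes, class confusion, and a confidence score driven by match quality —
so the evaluation and penalizing stages can be exercised without trained
CNN weights. Every stochastic operation is a pure function of its inputs
and a seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import yaml

from .annotations import (
    AnnotatedInstance,
    AnnotationCategory,
    BBox,
    DetectionClass,
    FrameRecord,
    Lighting,
    to_detection_class,
)
from .detection import Detection
from .geometry import PenGeometry, default_geometry

__all__ = [
    "SimConfig",
    "DetectionNoise",
    "SimulationError",
    "simulate_pen",
    "render_frame",
    "perturb_to_detections",
    "load_config",
]

_CATEGORIES = list(AnnotationCategory)
_CAT_INDEX = {c: i for i, c in enumerate(_CATEGORIES)}
_DRINK = _CAT_INDEX[AnnotationCategory.DRINKING]
_FEED = _CAT_INDEX[AnnotationCategory.FEEDING]

#: Box dimensions per category as (length-factor, width-factor) multiples of
#: (pig_length, pig_width). Lying/sitting pigs render shorter and wider so a
#: shape cue (box aspect) separates postures for the baseline detector.
_SHAPE_FACTORS: dict[AnnotationCategory, tuple[float, float]] = {
    AnnotationCategory.STANDING: (1.0, 1.0),
    AnnotationCategory.LYING_LATERAL: (0.9, 1.7),
    AnnotationCategory.LYING_STERNAL: (0.85, 1.5),
    AnnotationCategory.SITTING: (0.7, 1.3),
    AnnotationCategory.DRINKING: (1.0, 1.0),
    AnnotationCategory.FEEDING: (1.0, 1.0),
}


class SimulationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class DetectionNoise:
    """Detector-error model applied to ground truth.

    ``confusion`` maps each true detection class to a row of predicted-class
    probabilities (None means the identity). Confidence of a surviving
    detection is the IoU between its jittered and true box (its match
    quality) plus Gaussian noise of ``confidence_sd``, clipped to [0, 1];
    with zero jitter and zero confidence noise every confidence is exactly 1.
    Spurious detections draw confidence uniformly from
    ``false_positive_confidence``.
    """

    localization_sd: float = 0.0
    miss_rate: float = 0.0
    false_positive_rate: float = 0.0
    confusion: Mapping[DetectionClass, Mapping[DetectionClass, float]] | None = None
    confidence_sd: float = 0.0
    false_positive_confidence: tuple[float, float] = (0.3, 0.9)

    def __post_init__(self) -> None:
        if self.localization_sd < 0:
            raise SimulationError("localization_sd must be >= 0")
        for name, p in (("miss_rate", self.miss_rate),):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} {p} outside [0, 1]")
        if self.false_positive_rate < 0:
            raise SimulationError("false_positive_rate must be >= 0")
        if self.confusion is not None:
            for cls, row in self.confusion.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise SimulationError(
                        f"confusion row for {DetectionClass(cls).value} sums to {total}, not 1"
                    )
                if any(p < 0 for p in row.values()):
                    raise SimulationError("confusion probabilities must be >= 0")

    @classmethod
    def identity(cls) -> "DetectionNoise":
        return cls()


#: Default per-category stay probabilities of the behavior chain. Dwell at
#: the 20 s cadence: lying bouts are long (stay 0.9 -> mean 10 frames,
#: ~3.3 min), drinking bouts short (stay 0.5 -> mean 2 frames, ~40 s).
DEFAULT_STAY: dict[AnnotationCategory, float] = {
    AnnotationCategory.STANDING: 0.80,
    AnnotationCategory.LYING_LATERAL: 0.90,
    AnnotationCategory.LYING_STERNAL: 0.90,
    AnnotationCategory.SITTING: 0.75,
    AnnotationCategory.DRINKING: 0.50,
    AnnotationCategory.FEEDING: 0.80,
}

#: Default entry weights. With transition rows stay*I + (1-stay)*w the
#: stationary distribution is pi_c proportional to w_c / (1 - stay_c);
#: these weights target realistic weaner time budgets of roughly
#: 30% standing, 30% lateral lying, 22% sternal lying, 9% sitting,
#: 8% feeding and 1.2% drinking of pig-frames.
DEFAULT_ENTRY_WEIGHTS: dict[AnnotationCategory, float] = {
    AnnotationCategory.STANDING: 0.0600,
    AnnotationCategory.LYING_LATERAL: 0.0300,
    AnnotationCategory.LYING_STERNAL: 0.0220,
    AnnotationCategory.SITTING: 0.0215,
    AnnotationCategory.FEEDING: 0.0160,
    AnnotationCategory.DRINKING: 0.0060,
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic pen.

    Defaults reproduce the study conditions: 10 pigs per pen, frames
    sampled at 0.05 frame/s over the 10:00-14:00 observation window
    (14,400 s -> 720 frames). ``treatment_multipliers`` scale the chain's
    entry weight of drinking/feeding/standing, emulating diet-driven
    behavioral shifts (e.g. increased drinking under elevated
    post-weaning-diarrhea risk).
    """

    n_pigs: int = 10
    pig_length: float = 100.0
    pig_width: float = 40.0
    frame_rate: float = 0.05
    duration: float = 14400.0
    stay_probabilities: Mapping[AnnotationCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_STAY)
    )
    entry_weights: Mapping[AnnotationCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTRY_WEIGHTS)
    )
    treatment_multipliers: Mapping[str, float] = field(default_factory=dict)
    feeder_spaces: int = 5
    lighting_schedule: str | Callable[[float], Lighting] = "rgb"
    noise: DetectionNoise = field(default_factory=DetectionNoise)
    visibility_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise SimulationError("n_pigs must be >= 1")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise SimulationError("frame_rate and duration must be positive")
        for key, m in self.treatment_multipliers.items():
            if key not in ("drinking", "feeding", "standing"):
                raise SimulationError(f"unknown treatment multiplier target {key!r}")
            if m <= 0:
                raise SimulationError(f"treatment multiplier for {key!r} must be positive")
        if self.feeder_spaces < 1:
            raise SimulationError("feeder_spaces must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * self.frame_rate))

    def _effective_entry_weights(self) -> np.ndarray:
        w = np.array([float(self.entry_weights[c]) for c in _CATEGORIES])
        if np.any(w < 0) or w.sum() <= 0:
            raise SimulationError("entry weights must be non-negative with positive sum")
        mult_target = {
            "drinking": AnnotationCategory.DRINKING,
            "feeding": AnnotationCategory.FEEDING,
            "standing": AnnotationCategory.STANDING,
        }
        for key, m in self.treatment_multipliers.items():
            w[_CAT_INDEX[mult_target[key]]] *= m
        return w / w.sum()

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 6x6 matrix: stay*I + (1-stay) x entry weights."""
        stay = np.array([float(self.stay_probabilities[c]) for c in _CATEGORIES])
        if np.any(stay < 0) or np.any(stay >= 1):
            raise SimulationError("stay probabilities must lie in [0, 1)")
        w = self._effective_entry_weights()
        P = stay[:, None] * np.eye(len(_CATEGORIES)) + (1 - stay)[:, None] * w[None, :]
        if not np.allclose(P.sum(axis=1), 1.0):
            raise SimulationError("transition matrix rows do not sum to 1")
        return P

    def stationary_distribution(self) -> np.ndarray:
        """Closed-form stationary law pi_c proportional to w_c/(1-stay_c)."""
        stay = np.array([float(self.stay_probabilities[c]) for c in _CATEGORIES])
        w = self._effective_entry_weights()
        pi = w / (1.0 - stay)
        return pi / pi.sum()

    def lighting_at(self, t: float) -> Lighting:
        if callable(self.lighting_schedule):
            return Lighting(self.lighting_schedule(t))
        if self.lighting_schedule == "alternating":
            # switch every half hour, emulating automatic sensor switching
            return Lighting.RGB if int(t // 1800) % 2 == 0 else Lighting.INFRARED
        return Lighting(self.lighting_schedule)

    def to_dict(self) -> dict[str, Any]:
        if callable(self.lighting_schedule):
            raise SimulationError("callable lighting schedules are not serializable")
        return {
            "n_pigs": self.n_pigs,
            "pig_length": self.pig_length,
            "pig_width": self.pig_width,
            "frame_rate": self.frame_rate,
            "duration": self.duration,
            "stay_probabilities": {c.value: float(v) for c, v in self.stay_probabilities.items()},
            "entry_weights": {c.value: float(v) for c, v in self.entry_weights.items()},
            "treatment_multipliers": dict(self.treatment_multipliers),
            "feeder_spaces": self.feeder_spaces,
            "lighting_schedule": self.lighting_schedule,
            "visibility_threshold": self.visibility_threshold,
            "seed": self.seed,
            "noise": {
                "localization_sd": self.noise.localization_sd,
                "miss_rate": self.noise.miss_rate,
                "false_positive_rate": self.noise.false_positive_rate,
                "confidence_sd": self.noise.confidence_sd,
                "false_positive_confidence": list(self.noise.false_positive_confidence),
                "confusion": None
                if self.noise.confusion is None
                else {
                    DetectionClass(k).value: {DetectionClass(k2).value: v2 for k2, v2 in row.items()}
                    for k, row in self.noise.confusion.items()
                },
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        d = dict(d)
        if "stay_probabilities" in d:
            d["stay_probabilities"] = {
                AnnotationCategory(k): v for k, v in d["stay_probabilities"].items()
            }
        if "entry_weights" in d:
            d["entry_weights"] = {AnnotationCategory(k): v for k, v in d["entry_weights"].items()}
        if "noise" in d and isinstance(d["noise"], Mapping):
            nd = dict(d["noise"])
            if nd.get("confusion"):
                nd["confusion"] = {
                    DetectionClass(k): {DetectionClass(k2): v2 for k2, v2 in row.items()}
                    for k, row in nd["confusion"].items()
                }
            if "false_positive_confidence" in nd:
                nd["false_positive_confidence"] = tuple(nd["false_positive_confidence"])
            d["noise"] = DetectionNoise(**nd)
        return cls(**d)


def load_config(path: str | Path) -> tuple[SimConfig, PenGeometry]:
    """Load a combined ``{"sim": ..., "geometry": ...}`` JSON/YAML file."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    sim = SimConfig.from_dict(doc.get("sim", {}))
    geometry = PenGeometry.from_dict(doc["geometry"]) if "geometry" in doc else default_geometry()
    return sim, geometry


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------


def _union_area(rects: Sequence[tuple[float, float, float, float]]) -> float:
    """Exact union area of axis-aligned rectangles via coordinate compression."""
    if not rects:
        return 0.0
    xs = np.unique([v for r in rects for v in (r[0], r[2])])
    ys = np.unique([v for r in rects for v in (r[1], r[3])])
    covered = np.zeros((len(xs) - 1, len(ys) - 1), dtype=bool)
    for x0, y0, x1, y1 in rects:
        i0, i1 = np.searchsorted(xs, [x0, x1])
        j0, j1 = np.searchsorted(ys, [y0, y1])
        covered[i0:i1, j0:j1] = True
    dx = np.diff(xs)
    dy = np.diff(ys)
    return float((dx[:, None] * dy[None, :])[covered].sum())


def visible_fractions(boxes: np.ndarray) -> np.ndarray:
    """Unoccluded area fraction per box; pigs placed later lie on top.

    ``boxes`` is (n, 4) corner format. Box i is occluded by the union of
    its intersections with boxes j > i.
    """
    n = len(boxes)
    vis = np.ones(n)
    for i in range(n - 1):
        xi0, yi0, xi1, yi1 = boxes[i]
        area_i = (xi1 - xi0) * (yi1 - yi0)
        inters = []
        for j in range(i + 1, n):
            x0 = max(xi0, boxes[j, 0])
            y0 = max(yi0, boxes[j, 1])
            x1 = min(xi1, boxes[j, 2])
            y1 = min(yi1, boxes[j, 3])
            if x1 > x0 and y1 > y0:
                inters.append((x0, y0, x1, y1))
        if inters:
            vis[i] = 1.0 - _union_area(inters) / area_i
    return vis


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _enforce_capacity(
    proposals: np.ndarray,
    previous: np.ndarray,
    category_index: int,
    capacity: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blocked entrants to a full resource revert to their previous state."""
    wanting = np.flatnonzero(proposals == category_index)
    if len(wanting) <= capacity:
        return proposals
    continuing = wanting[previous[wanting] == category_index]
    newcomers = wanting[previous[wanting] != category_index]
    slots = capacity - len(continuing)
    if slots < len(newcomers):
        admitted = rng.choice(newcomers, size=max(slots, 0), replace=False)
        blocked = np.setdiff1d(newcomers, admitted)
        proposals = proposals.copy()
        proposals[blocked] = previous[blocked]
    return proposals


def _place_centers(
    states: np.ndarray,
    dims: np.ndarray,
    geometry: PenGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample box centers: resource zones for drinking/feeding pigs,
    uniform inside the (inset) pen otherwise."""
    n = len(states)
    centers = np.empty((n, 2))
    pen = geometry.pen
    for i in range(n):
        w, h = dims[i]
        if states[i] == _DRINK:
            zone = geometry.drinker_zones[int(rng.integers(len(geometry.drinker_zones)))]
        elif states[i] == _FEED:
            zone = geometry.feeder_zones[int(rng.integers(len(geometry.feeder_zones)))]
        else:
            zone = None
        if zone is not None:
            # center anywhere in the zone, but keep the box inside the pen
            lox = max(zone.xmin, pen.xmin + w / 2)
            hix = min(zone.xmax, pen.xmax - w / 2)
            loy = max(zone.ymin, pen.ymin + h / 2)
            hiy = min(zone.ymax, pen.ymax - h / 2)
            if lox > hix:
                lox = hix = 0.5 * (zone.xmin + zone.xmax)
            if loy > hiy:
                loy = hiy = 0.5 * (zone.ymin + zone.ymax)
        else:
            lox, hix = pen.xmin + w / 2, pen.xmax - w / 2
            loy, hiy = pen.ymin + h / 2, pen.ymax - h / 2
        centers[i, 0] = rng.uniform(lox, hix) if hix > lox else lox
        centers[i, 1] = rng.uniform(loy, hiy) if hiy > loy else loy
    return centers


def simulate_pen(
    config: SimConfig, geometry: PenGeometry, pen_id: str = "pen-1"
) -> list[FrameRecord]:
    """Generate the ground-truth annotation stream of one pen recording.

    Deterministic given (config, geometry, seed). The number of frames is
    ``floor(duration * frame_rate)``; each pig carries exactly one category
    per frame; drinking (feeding) pigs have their box center inside a
    drinker (feeder) zone; instances occluded below the visibility
    threshold are dropped, mirroring the annotation protocol.
    """
    rng = np.random.default_rng(config.seed)
    P = config.transition_matrix()
    pi = config.stationary_distribution()
    n = config.n_pigs
    n_frames = config.n_frames
    drink_cap = max(len(geometry.drinker_zones), 1)

    states = rng.choice(len(_CATEGORIES), size=n, p=pi)
    # initial draw must already respect resource capacities
    states = _enforce_capacity(states, np.full(n, _CAT_INDEX[AnnotationCategory.STANDING]),
                               _DRINK, drink_cap, rng)
    states = _enforce_capacity(states, np.full(n, _CAT_INDEX[AnnotationCategory.STANDING]),
                               _FEED, config.feeder_spaces, rng)

    stay = np.array([float(config.stay_probabilities[c]) for c in _CATEGORIES])
    w = config._effective_entry_weights()
    frame_dt = 1.0 / config.frame_rate
    base_dims = np.array(
        [
            (
                config.pig_length * _SHAPE_FACTORS[c][0],
                config.pig_width * _SHAPE_FACTORS[c][1],
            )
            for c in _CATEGORIES
        ]
    )

    frames: list[FrameRecord] = []
    for t in range(n_frames):
        if t > 0:
            keep = rng.random(n) < stay[states]
            fresh = rng.choice(len(_CATEGORIES), size=n, p=w)
            proposals = np.where(keep, states, fresh)
            proposals = _enforce_capacity(proposals, states, _DRINK, drink_cap, rng)
            proposals = _enforce_capacity(proposals, states, _FEED, config.feeder_spaces, rng)
            # a feeding-blocked pig may have reverted into the drinker; final pass
            proposals = _enforce_capacity(proposals, states, _DRINK, drink_cap, rng)
            states = proposals

        # orientation: long axis along x or y, chosen per pig per frame
        horizontal = rng.random(n) < 0.5
        d = base_dims[states].copy()
        d[~horizontal] = d[~horizontal][:, ::-1]
        centers = _place_centers(states, d, geometry, rng)
        boxes = np.column_stack(
            [
                centers[:, 0] - d[:, 0] / 2,
                centers[:, 1] - d[:, 1] / 2,
                centers[:, 0] + d[:, 0] / 2,
                centers[:, 1] + d[:, 1] / 2,
            ]
        )
        vis = visible_fractions(boxes)
        timestamp = t * frame_dt
        instances = tuple(
            AnnotatedInstance(
                box=BBox(*boxes[i]),
                category=_CATEGORIES[states[i]],
                pig_id=i,
                visible_fraction=float(vis[i]),
            )
            for i in range(n)
            if vis[i] >= config.visibility_threshold
        )
        frames.append(
            FrameRecord(
                frame_index=t,
                timestamp=timestamp,
                lighting=config.lighting_at(timestamp),
                pen_id=pen_id,
                instances=instances,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FLOOR_GRAY = 70.0
_WALL_GRAY = 40.0
_ZONE_GRAY = 95.0
_PIG_GRAY = 205.0
_PIG_RGB = (230, 190, 180)
_FLOOR_RGB = (70, 72, 76)
_WALL_RGB = (40, 40, 42)
_ZONE_RGB = (95, 95, 100)


def render_frame(frame: FrameRecord, geometry: PenGeometry, style: str | Lighting | None = None) -> np.ndarray:
    """Rasterize a frame: one filled ellipse per pig on a textured floor.

    ``style`` defaults to the frame's own lighting mode. RGB frames are
    (H, W, 3) uint8, infrared frames single-channel (H, W) uint8 — pigs
    stay brighter than floor and zone markings in both so a simple
    intensity threshold separates them. Rendering is deliberately schematic
    (photorealism is a non-goal); it exists to exercise the classical
    baseline detector.
    """
    from skimage.draw import ellipse as draw_ellipse

    style = Lighting(style) if style is not None else frame.lighting
    pen = geometry.pen
    height = int(math.ceil(pen.ymax + pen.ymin))
    width = int(math.ceil(pen.xmax + pen.xmin))
    gray = np.full((height, width), _WALL_GRAY)
    r0, r1 = int(pen.ymin), int(pen.ymax)
    c0, c1 = int(pen.xmin), int(pen.xmax)
    gray[r0:r1, c0:c1] = _FLOOR_GRAY
    # deterministic floor texture, tied to the frame index
    texture_rng = np.random.default_rng(frame.frame_index + 1)
    gray[r0:r1, c0:c1] += texture_rng.uniform(0, 12, size=(r1 - r0, c1 - c0))
    for zone in (*geometry.feeder_zones, *geometry.drinker_zones):
        zr0, zr1 = int(zone.ymin), int(zone.ymax)
        zc0, zc1 = int(zone.xmin), int(zone.xmax)
        gray[zr0:zr1, zc0:zc1] = _ZONE_GRAY

    pig_mask = np.zeros((height, width), dtype=bool)
    for inst in frame.instances:
        b = inst.box
        cy, cx = (b.ymin + b.ymax) / 2, (b.xmin + b.xmax) / 2
        rr, cc = draw_ellipse(cy, cx, b.height / 2, b.width / 2, shape=gray.shape)
        pig_mask[rr, cc] = True

    if style is Lighting.INFRARED:
        out = gray.copy()
        out[pig_mask] = _PIG_GRAY
        return np.clip(out, 0, 255).astype(np.uint8)
    rgb = np.empty((height, width, 3))
    scale = gray / _FLOOR_GRAY
    for ch in range(3):
        rgb[..., ch] = _FLOOR_RGB[ch] * scale
        rgb[..., ch][pig_mask] = _PIG_RGB[ch]
    return np.clip(rgb, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# detection-noise model
# ---------------------------------------------------------------------------


def _confusion_rows(noise: DetectionNoise) -> dict[DetectionClass, tuple[list[DetectionClass], np.ndarray]]:
    rows = {}
    for cls in DetectionClass:
        if noise.confusion is None or cls not in noise.confusion:
            rows[cls] = ([cls], np.array([1.0]))
        else:
            row = noise.confusion[cls]
            keys = list(row)
            rows[cls] = (keys, np.array([row[k] for k in keys]))
    return rows


def perturb_to_detections(
    frames: Sequence[FrameRecord],
    noise: DetectionNoise,
    seed: int,
) -> list[tuple[int, list[Detection]]]:
    """Turn ground truth into detector-like output under a noise model.

    Each surviving ground-truth instance yields one detection with a
    jittered box, a possibly confused class and a match-quality-driven
    confidence; instances are missed with probability ``miss_rate`` and
    Poisson(``false_positive_rate``) spurious detections are added per
    frame. Deterministic given (frames, noise, seed).
    """
    from .evaluation import iou as _iou  # local import avoids module cycle

    rng = np.random.default_rng(seed)
    rows = _confusion_rows(noise)
    result: list[tuple[int, list[Detection]]] = []
    for fr in frames:
        dets: list[Detection] = []
        for inst in fr.instances:
            if noise.miss_rate > 0 and rng.random() < noise.miss_rate:
                continue
            b = inst.box
            if noise.localization_sd > 0:
                jitter = rng.normal(0.0, noise.localization_sd, size=4)
                x0, y0, x1, y1 = np.array(b.as_corner_list()) + jitter
                if x1 <= x0:
                    x0, x1 = min(x0, x1), min(x0, x1) + 1.0
                if y1 <= y0:
                    y0, y1 = min(y0, y1), min(y0, y1) + 1.0
                jb = BBox(x0, y0, x1, y1)
                quality = _iou(jb, b)
            else:
                jb = b
                quality = 1.0
            keys, probs = rows[inst.detection_class]
            cls = keys[int(rng.choice(len(keys), p=probs))] if len(keys) > 1 else keys[0]
            if noise.confidence_sd > 0:
                conf = float(np.clip(quality + rng.normal(0.0, noise.confidence_sd), 0.0, 1.0))
            else:
                conf = float(min(quality, 1.0))
            dets.append(Detection(box=jb, detection_class=cls, confidence=conf))
        if noise.false_positive_rate > 0:
            for _ in range(int(rng.poisson(noise.false_positive_rate))):
                dets.append(_spurious_detection(fr, rng, noise))
        result.append((fr.frame_index, dets))
    return result


def _spurious_detection(
    frame: FrameRecord, rng: np.random.Generator, noise: DetectionNoise
) -> Detection:
    """A false positive: a pig-sized box anywhere pigs could plausibly be."""
    if frame.instances:
        ref = frame.instances[int(rng.integers(len(frame.instances)))].box
        w, h = ref.width, ref.height
        lo_x, hi_x = min(i.box.xmin for i in frame.instances), max(i.box.xmax for i in frame.instances)
        lo_y, hi_y = min(i.box.ymin for i in frame.instances), max(i.box.ymax for i in frame.instances)
    else:
        w, h = 100.0, 40.0
        lo_x, hi_x, lo_y, hi_y = 0.0, 600.0, 0.0, 320.0
    x0 = rng.uniform(lo_x, max(hi_x - w, lo_x + 1.0))
    y0 = rng.uniform(lo_y, max(hi_y - h, lo_y + 1.0))
    cls = list(DetectionClass)[int(rng.integers(len(DetectionClass)))]
    conf = float(rng.uniform(*noise.false_positive_confidence))
    return Detection(box=BBox(x0, y0, x0 + w, y0 + h), detection_class=cls, confidence=conf)
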