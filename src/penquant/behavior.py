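"""Behavior indices and their aggregation across pens, days and treatments.

The behavior index of behavior *i* over a video segment of N frames is

    BI_i = (1/N) * sum_{k=1..N} OBF_k,

where OBF_k is the occurrence of the behavior at the k-th frame — here the
COUNT of pigs showing it (so a pen of 10 pigs all standing in every frame
scores a standing index of 10). Normalizing by the frame count makes
indices comparable across recordings with variable frame rates and
segment lengths. Frames with no detection of the behavior contribute zero
and are included in N.

Indices are computed from post-penalization, post-confidence-threshold
detections: the penalizing stage sits between detection and
quantification. Treatment comparison here is descriptive (quartile
summaries suitable for box plots) plus Pearson correlations between
indices; mixed-model inference is routine off-the-shelf statistics and
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import DetectionClass
from .detection import Detection

__all__ = [
    "BehaviorIndexRecord",
    "behavior_index",
    "index_table",
    "pearson_r",
    "treatment_summary",
    "records_to_frame",
    "write_index_csv",
]

_BEHAVIOR_ORDER = list(DetectionClass)


@dataclass(frozen=True)
class BehaviorIndexRecord:
    """One pen x day x behavior index value (pig-occurrences per frame)."""

    pen_id: str
    day: int
    behavior: DetectionClass
    index_value: float
    n_frames: int
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.index_value < 0:
            raise ValueError("index_value must be non-negative")


FrameDetections = Mapping[int, Sequence[Detection]] | Sequence[Sequence[Detection]]


def _frame_counts(detections: FrameDetections, behavior: DetectionClass) -> list[int]:
    if isinstance(detections, Mapping):
        frames = detections.values()
    else:
        frames = detections
    return [sum(1 for d in frame if d.detection_class == behavior) for frame in frames]


def behavior_index(
    detections: FrameDetections,
    behavior: DetectionClass,
    n_frames: int,
    *,
    pen_id: str = "pen",
    day: int = 0,
    treatment: str | None = None,
    occurrence: str = "count",
) -> BehaviorIndexRecord:
    """Compute one behavior index.

    ``n_frames`` is the total number of frames in the analyzed window,
    including frames with zero detections (``detections`` may omit them).
    ``occurrence="count"`` (default) counts pigs per frame;
    ``"indicator"`` scores a frame 0/1 for presence of the behavior.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    counts = _frame_counts(detections, behavior)
    if len(counts) > n_frames:
        raise ValueError(
            f"{len(counts)} frames of detections exceed the declared window of {n_frames}"
        )
    if occurrence == "count":
        total = sum(counts)
    elif occurrence == "indicator":
        total = sum(1 for c in counts if c > 0)
    else:
        raise ValueError(f"unknown occurrence mode {occurrence!r}")
    return BehaviorIndexRecord(
        pen_id=pen_id,
        day=day,
        behavior=behavior,
        index_value=total / n_frames,
        n_frames=n_frames,
        treatment=treatment,
    )


def index_table(
    detections_by_pen_day: Mapping[tuple[str, int], FrameDetections],
    assignment: Mapping[str, str],
    n_frames: int | Mapping[tuple[str, int], int],
    behaviors: Sequence[DetectionClass] = tuple(_BEHAVIOR_ORDER),
    *,
    occurrence: str = "count",
) -> list[BehaviorIndexRecord]:
    """One record per pen x day x behavior, labeled with treatments.

    Ordering is deterministic: pens sorted, then days, then behaviors in
    class order. Every pen must appear in ``assignment``.
    """
    records: list[BehaviorIndexRecord] = []
    for pen_id, day in sorted(detections_by_pen_day):
        if pen_id not in assignment:
            raise KeyError(f"pen {pen_id!r} has no treatment assignment")
        N = n_frames[(pen_id, day)] if isinstance(n_frames, Mapping) else n_frames
        for behavior in behaviors:
            records.append(
                behavior_index(
                    detections_by_pen_day[(pen_id, day)],
                    behavior,
                    N,
                    pen_id=pen_id,
                    day=day,
                    treatment=assignment[pen_id],
                    occurrence=occurrence,
                )
            )
    return records


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def records_to_frame(records: Sequence[BehaviorIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pen_id": [r.pen_id for r in records],
            "day": [r.day for r in records],
            "treatment": [r.treatment for r in records],
            "behavior": [r.behavior.value for r in records],
            "n_frames": [r.n_frames for r in records],
            "index_value": [r.index_value for r in records],
        }
    )


def treatment_summary(records: Sequence[BehaviorIndexRecord]) -> pd.DataFrame:
    """Quartile summary per treatment x day x behavior.

    Quartiles use the median-inclusive linear-interpolation convention
    (numpy's default, type 7), the values a box plot draws: Q1, median,
    Q3, plus mean and n.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    grouped = df.groupby(["treatment", "day", "behavior"])["index_value"]
    out = grouped.agg(
        n="count",
        mean="mean",
        q1=lambda v: float(np.quantile(v, 0.25)),
        median="median",
        q3=lambda v: float(np.quantile(v, 0.75)),
    ).reset_index()
    out.attrs["quantile_convention"] = "linear interpolation (type 7)"
    return out


def write_index_csv(records: Sequence[BehaviorIndexRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
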