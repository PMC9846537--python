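"""Detection evaluation: IoU, confidence-ranked matching, precision-recall
curves, per-class average precision (AP50) and mAP.

Average precision is the area under the precision-recall curve,

    AP = integral over r in [0, 1] of p(r) dr,

realized discretely with all-point (precision-envelope) interpolation: the
envelope ``p_env(r) = max_{r' >= r} p(r')`` is integrated exactly over the
achieved recall levels. Matching follows the standard AP50 contract:
detections are ranked by descending confidence and greedily matched,
per frame and class-exact, to the unmatched ground-truth box of highest
IoU at or above the threshold (0.5 for AP50); unmatched and duplicate
detections are false positives. AP is computed on the full ranked list —
the deployment confidence threshold is a separate filtering rule and is
not applied here, since a truncated ranking cannot reach recall 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import BBox, DetectionClass, FrameRecord, to_detection_class
from .detection import Detection

__all__ = [
    "iou",
    "MatchResult",
    "PRCurve",
    "APResult",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "plot_pr",
]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """Ranked TP/FP flags for one detection class.

    ``flags[k]`` is True iff the k-th ranked detection (descending
    confidence) matched a previously unmatched ground-truth box at
    IoU >= ``iou_threshold``.
    """

    detection_class: DetectionClass
    flags: tuple[bool, ...]
    confidences: tuple[float, ...]
    n_ground_truth: int
    iou_threshold: float

    @property
    def n_true_positive(self) -> int:
        return sum(self.flags)

    @property
    def n_false_positive(self) -> int:
        return len(self.flags) - self.n_true_positive


@dataclass(frozen=True)
class PRCurve:
    """Running (recall, precision) points along the ranked detection list."""

    detection_class: DetectionClass
    recalls: tuple[float, ...]
    precisions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(r2 < r1 for r1, r2 in zip(self.recalls, self.recalls[1:])):
            raise ValueError("recall must be non-decreasing along the ranking")


@dataclass(frozen=True)
class APResult:
    per_class: Mapping[DetectionClass, float]
    mean: float
    interpolation: str = "all_point_envelope"


def _truth_boxes_by_frame(
    truth: Sequence[FrameRecord], detection_class: DetectionClass
) -> dict[int, list[BBox]]:
    by_frame: dict[int, list[BBox]] = {}
    for fr in truth:
        by_frame[fr.frame_index] = [
            inst.box for inst in fr.instances if inst.detection_class == detection_class
        ]
    return by_frame


def match_detections(
    detections: Mapping[int, Sequence[Detection]],
    truth: Sequence[FrameRecord],
    detection_class: DetectionClass,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ranked matching for one class.

    Ties in confidence are broken by the detection's best static IoU
    against any same-frame same-class ground-truth box, then by input
    order, so the ranking is fully deterministic.
    """
    gt = _truth_boxes_by_frame(truth, detection_class)
    ranked: list[tuple[float, float, int, int, Detection]] = []
    order = 0
    for fi in detections:
        if fi not in gt:
            raise KeyError(f"detections reference frame {fi} absent from ground truth")
        for det in detections[fi]:
            if det.detection_class != detection_class:
                continue
            best = max((iou(det.box, b) for b in gt[fi]), default=0.0)
            ranked.append((-det.confidence, -best, order, fi, det))
            order += 1
    ranked.sort(key=lambda t: t[:3])

    matched: dict[int, list[bool]] = {fi: [False] * len(boxes) for fi, boxes in gt.items()}
    flags: list[bool] = []
    confs: list[float] = []
    for _negconf, _negiou, _order, fi, det in ranked:
        best_j, best_iou = -1, iou_threshold
        for j, box in enumerate(gt[fi]):
            if matched[fi][j]:
                continue
            v = iou(det.box, box)
            if v >= best_iou and (best_j == -1 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[fi][best_j] = True
            flags.append(True)
        else:
            flags.append(False)
        confs.append(det.confidence)
    n_gt = sum(len(b) for b in gt.values())
    return MatchResult(
        detection_class=detection_class,
        flags=tuple(flags),
        confidences=tuple(confs),
        n_ground_truth=n_gt,
        iou_threshold=iou_threshold,
    )


def pr_curve(match: MatchResult) -> PRCurve:
    """Running precision/recall over the ranked list.

    Point k (1-based) has precision TP@k / k and recall TP@k / n_gt.
    """
    if match.n_ground_truth == 0:
        raise ValueError(
            f"{match.detection_class.value}: no ground-truth instances; recall undefined"
        )
    tp = np.cumsum(match.flags)
    k = np.arange(1, len(match.flags) + 1)
    return PRCurve(
        detection_class=match.detection_class,
        recalls=tuple(tp / match.n_ground_truth),
        precisions=tuple(tp / k),
    )


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope over recall.

    Equals the sum over achieved recall levels of
    ``(r_k - r_{k-1}) * p_env(r_k)`` where ``p_env`` is the running
    maximum of precision taken from the right.
    """
    if not curve.recalls:
        return 0.0
    r = np.concatenate([[0.0], np.asarray(curve.recalls)])
    p = np.concatenate([[0.0], np.asarray(curve.precisions)])
    # precision envelope: best precision at any recall >= r
    env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * env[1:]))


def mean_ap(per_class: Mapping[DetectionClass, float]) -> float:
    """Unweighted mean of per-class APs over classes with ground truth."""
    if not per_class:
        raise ValueError("mean_ap of an empty class mapping is undefined")
    values = list(per_class.values())
    return float(sum(values) / len(values))


def evaluate_detections(
    detections: Mapping[int, Sequence[Detection]],
    truth: Sequence[FrameRecord],
    iou_threshold: float = 0.5,
) -> tuple[APResult, dict[DetectionClass, PRCurve], dict[DetectionClass, MatchResult]]:
    """Full per-class evaluation.

    Classes with zero ground-truth instances are excluded from the result
    (rather than scored 0), so a recording without drinking events does
    not drag the mAP down.
    """
    per_class: dict[DetectionClass, float] = {}
    curves: dict[DetectionClass, PRCurve] = {}
    matches: dict[DetectionClass, MatchResult] = {}
    for cls in DetectionClass:
        match = match_detections(detections, truth, cls, iou_threshold)
        if match.n_ground_truth == 0:
            continue
        curve = pr_curve(match)
        per_class[cls] = average_precision(curve)
        curves[cls] = curve
        matches[cls] = match
    if not per_class:
        raise ValueError("no detection class has ground-truth instances")
    return APResult(per_class=per_class, mean=mean_ap(per_class)), curves, matches


def plot_pr(curves: Sequence[PRCurve], path: str | Path) -> None:
    """One precision-recall panel per class, AP annotated, axes [0,1]^2."""
    if not curves:
        raise ValueError("no curves to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    ncols = min(n, 2)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4 * nrows), squeeze=False)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, curve in zip(axes.flat, curves):
        ap = average_precision(curve)
        ax.plot([0.0, *curve.recalls], [1.0, *curve.precisions], drawstyle="steps-post")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"{curve.detection_class.value}  AP50 = {ap:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
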