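"""Independent brute-force oracles used to cross-check the evaluators.

Deliberately naive: no cumulative tricks, no vectorization — every
quantity is recomputed from first principles at each step so the oracle
shares no code path with the package implementation.
"""

from __future__ import annotations


def ap_bruteforce(flags: list[bool], n_ground_truth: int) -> float:
    """Average precision by enumerating every rank cut-off.

    For each prefix of the ranked TP/FP flags compute (recall, precision)
    from scratch; then integrate the precision envelope
    ``p_env(r) = max{precision at any recall >= r}`` over the achieved
    recall levels.
    """
    if n_ground_truth <= 0:
        raise ValueError("need ground truth")
    points = []
    for k in range(1, len(flags) + 1):
        tp = sum(1 for f in flags[:k] if f)
        points.append((tp / n_ground_truth, tp / k))
    ap = 0.0
    prev_r = 0.0
    for r in sorted({r for r, _ in points}):
        if r == 0.0:
            continue
        p_env = max(p for r2, p in points if r2 >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def behavior_index_bruteforce(per_frame_counts: list[int], n_frames: int) -> float:
    """Hand-summed behavior index: plain running total over frames."""
    total = 0
    for c in per_frame_counts:
        total = total + c
    return total / n_frames
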