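"""Score a noisy detector against simulated ground truth.

Applies a detector-error model (box jitter, 8% misses, spurious boxes,
mild standing/non-standing confusion) to a simulated recording and
computes per-class AP50 and mAP. AP is the area under the
precision-recall curve per class; 1.0 means every ground-truth box was
found before the first false positive.
"""

from penquant import (
    DetectionClass,
    DetectionNoise,
    SimConfig,
    default_geometry,
    evaluate_detections,
    perturb_to_detections,
    plot_pr,
    simulate_pen,
)

geometry = default_geometry()
frames = simulate_pen(SimConfig(seed=7), geometry)
noise = DetectionNoise(
    localization_sd=4.0,
    miss_rate=0.08,
    false_positive_rate=0.4,
    confidence_sd=0.05,
    confusion={
        DetectionClass.STANDING: {
            DetectionClass.STANDING: 0.9,
            DetectionClass.NON_STANDING: 0.1,
        }
    },
)
detections = dict(perturb_to_detections(frames, noise, seed=1))

ap, curves, matches = evaluate_detections(detections, frames, iou_threshold=0.5)
for cls, value in ap.per_class.items():
    m = matches[cls]
    print(f"  {cls.value:14s} AP50 = {value:.3f}  (TP {m.n_true_positive}, "
          f"FP {m.n_false_positive}, GT {m.n_ground_truth})")
print(f"  mAP = {ap.mean:.3f}")
plot_pr(list(curves.values()), "pr_curves.png")
print("wrote pr_curves.png (one precision-recall panel per class)")
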