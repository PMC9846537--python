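"""Behavior indices across treatment arms of a simulated trial.

Three dietary arms (T1 ZnO, T2 unsupplemented control, T3 antibiotic),
two pens each, three observation days. The control arm's pigs enter
drinking 1.5x more often — emulating the extra water intake that
accompanies post-weaning diarrhea risk — and that shows up directly in
the drinking behavior index (pig-occurrences per frame, Eq.-style
cumulative count normalized by frame count).
"""

import zlib

from penquant import (
    Detection,
    DetectionClass,
    SimConfig,
    default_geometry,
    index_table,
    simulate_pen,
    treatment_summary,
)

geometry = default_geometry()
arms = {"T1": {}, "T2": {"drinking": 1.5}, "T3": {}}
assignment = {}
detections = {}
for arm, multipliers in arms.items():
    for p in (1, 2):
        pen = f"{arm}-pen{p}"
        assignment[pen] = arm
        for day in (2, 4, 6):
            cfg = SimConfig(seed=zlib.crc32(f"{arm}:{p}:{day}".encode()) % 2**31,
                            treatment_multipliers=multipliers)
            frames = simulate_pen(cfg, geometry, pen_id=pen)
            detections[(pen, day)] = {
                fr.frame_index: [
                    Detection(box=i.box, detection_class=i.detection_class, confidence=1.0)
                    for i in fr.instances
                ]
                for fr in frames
            }

records = index_table(detections, assignment, n_frames=SimConfig().n_frames)
print(f"{len(records)} index records (pens x days x behaviors)")
summary = treatment_summary(records)
drinking = summary[summary["behavior"] == "drinking"]
print("\nDrinking index by treatment and day (mean over pens):")
for _, row in drinking.iterrows():
    print(f"  {row['treatment']} day {row['day']}: mean {row['mean']:.3f} "
          f"(Q1 {row['q1']:.3f}, median {row['median']:.3f}, Q3 {row['q3']:.3f})")
t_means = drinking.groupby("treatment")["mean"].mean()
print(f"\nT2/T1 drinking ratio: {t_means['T2'] / t_means['T1']:.2f} "
      "(configured entry multiplier 1.5; drinker-capacity contention "
      "compresses the realized ratio slightly)")
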