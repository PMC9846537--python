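# Methods

This note documents the models, conventions and design choices behind
`penquant`: what each stage computes, which parameters matter, what the
synthetic data does and does not emulate, and the numerical details a
user reproducing results will care about.

## Annotation model

A frame holds zero or more annotated instances; an instance is an
axis-aligned box `[xmin, ymin, xmax, ymax]` in continuous pixels (origin
top-left, y down) plus one of six behavior/posture categories:
`standing`, `non_standing_lying_lateral`, `non_standing_lying_sternal`,
`non_standing_sitting`, `drinking`, `feeding`. Drinking and feeding take
precedence over posture — an instance carries exactly one label. The six
categories collapse onto four detection classes (the three non-standing
variants merge), which is the granularity the detector, penalizer,
evaluator and indices all operate at. Keeping lateral and sternal lying
distinct at annotation level costs nothing and preserves ethogram detail
for simulation.

Box area is `(xmax − xmin)(ymax − ymin)` with no inclusive-pixel `+1`;
this keeps IoU free of discretization conventions. The annotation
protocol's visibility rule is part of the data model: an instance exists
only if at least half of the pig's body is unoccluded
(`visible_fraction ≥ 0.5`); files that omit the field default it to 1.0
because real detector output carries no occlusion estimate.

Two dialects round-trip losslessly: a COCO-style JSON (`bbox` as
`[x, y, w, h]`, six categories, per-image `pen_id`/`lighting`/
`timestamp`) for interoperability, and a flat CSV storing the corner
format directly, one row per instance (empty frames keep a placeholder
row so frame counts survive the round trip).

## Pen simulator

**Behavior dynamics.** Each pig is an independent discrete-time Markov
chain over the six categories, stepped once per sampled frame (20 s at
the default 0.05 frame/s). Transition rows are
`P(c→c′) = s_c·δ_{cc′} + (1 − s_c)·w̃_{c′}`: with probability `s_c` the
pig stays put, otherwise it re-draws a state from the shared entry-weight
vector `w`. The stationary law is closed-form, `π_c ∝ w_c/(1 − s_c)`,
which makes the defaults auditable. They target a realistic weaner
daytime budget: ≈30% standing, ≈30% lateral lying, ≈22% sternal lying,
≈9% sitting, ≈8% feeding and ≈1.2% drinking of pig-frames, with long
lying bouts (`s = 0.9`, mean ≈3.3 min), short drinking visits
(`s = 0.5`, mean ≈40 s) and intermediate feeding bouts (`s = 0.8`).
Treatment effects multiply the entry weight of drinking, feeding or
standing, so a 1.5× drinking multiplier scales the unconstrained
stationary drinking fraction by almost exactly 1.5 (the weight
renormalization contributes < 1%).

**Resource capacity.** The pen has one bowl drinker (capacity one pig)
and a multi-space feeder (capacity `feeder_spaces`, default 5). A pig
whose chain proposes an occupied resource stays in its previous state;
continuing occupants keep their slot. This produces the observable "at
most one drinking instance per frame" structure of a one-drinker pen.
Contention slightly compresses treatment effects on the *realized*
drinking index: from an occupancy balance, a configured 1.5× entry
multiplier yields a measured index ratio of ≈1.4 at the default rates —
the parameter-recovery checks account for this rather than tune it away.

**Placement and occlusion.** Positions are re-sampled uniformly within
the pen every frame (at 20 s spacing, frame-to-frame spatial correlation
adds nothing to the statistics the indices use); drinking/feeding pigs
are placed with box centers inside their zone. Lying and sitting pigs
get wider, shorter boxes than standing ones, giving the renderer a shape
cue. Occlusion follows stacking order: pigs placed later lie on top, the
occluded fraction of a box is the exact union area of its intersections
with later boxes (computed by coordinate compression), and instances
below the visibility threshold are dropped from the annotation.

**Rendering and baseline detector.** Frames render as filled ellipses on
a textured floor, RGB (3-channel) or infrared (single-channel), with
zone markings kept darker than pigs. This is deliberately schematic —
its only job is to support a classical detector: intensity threshold,
connected components, component bounding boxes; class from zone
membership (drinking/feeding) or box aspect ratio ≥ 1.8 (standing vs.
non-standing); confidence the saturating function
`area/(area + 800 px²)` of component area. Overlapping pigs merge into
one component — the detector is honest about being a desk-scale
stand-in, and tests that need exact recovery use disjoint layouts.

**Detection noise.** Ground truth becomes detector-like output by:
per-instance miss with probability `miss_rate`; Gaussian corner jitter
(`localization_sd` px); class confusion by a row-stochastic matrix;
confidence = IoU between jittered and true box plus Gaussian noise
(`confidence_sd`), clipped to [0, 1]; Poisson(`false_positive_rate`)
pig-sized spurious boxes per frame with uniform confidences (default
0.3–0.9). The identity setting reproduces ground truth with confidence
exactly 1, which pins down the zero-noise end-to-end contract: AP⁵⁰ = 1
per class and nothing for the penalizer to remove.

**What the simulator does not emulate.** Real pigs are socially
correlated, move smoothly, and huddle; lighting changes photometrics
continuously rather than switching a render style; a trained CNN's
errors are structured (scale- and pose-dependent), not i.i.d. Passing
tests therefore demonstrate the correctness of the *analysis machinery*
under controlled statistical structure — not field performance of any
detector on farm video.

## Detection pipeline conventions

- **Confidence filter:** strictly greater-than the threshold (default
  0.5) — a detection at exactly the threshold is dropped. This is a
  deployment rule; it is not applied when computing AP.
- **Warm-up schedule:** `lr(i) = base_lr · (i/warmup)⁴` for
  `i < warmup`, constant `base_lr` thereafter (defaults `1e-3`, 1000
  iterations). The ramp is exact at the boundary and monotone.
  Remaining training parameters (momentum 0.9, weight decay 5e-4, batch
  64, mini-batch 8, 100 epochs) are carried in `ScheduleParams` for
  configuration completeness; no network training ships.
- **Augmentation:** horizontal flip (x mirrored about the image center,
  an involution), uniform scaling (boxes multiplied, clipped to the
  canvas, dropped when degenerate), HSV jitter (saturation/brightness/
  contrast; boxes untouched; all-zero deltas are a pixel-exact no-op).
- **Detector contract:** stateless and frame-synchronous; no temporal
  smoothing anywhere, so an error in one frame has no consequences for
  the next.

## Penalizer

Default rule `center_in_zone` with zones dilated by a margin of half a
pig length (50 px at defaults): robust to box-size jitter and
threshold-free. The alternative `box_overlap_fraction(τ)` requires a
fraction τ of the box area inside a zone. Default action `drop`;
`reclassify_to_posture` is available since a penalized pig still has a
posture. Guaranteed algebra: idempotent; posture classes exactly
conserved; output ⊆ input (drop action) with order preserved; retained
count non-decreasing in the margin. Pen geometry is mandatory per pen —
sources sit at different positions in different pens — and a missing
zone for a behavior actually present is a configuration error, not a
silent pass.

## Evaluation

Matching is per-frame and class-exact: detections sorted by descending
confidence (ties broken by best static IoU, then input order — fully
deterministic), each greedily taking the unmatched ground-truth box of
highest IoU ≥ threshold (0.5 for AP⁵⁰); unmatched and duplicate
detections are false positives. AP integrates the precision envelope
`p_env(r) = max_{r′≥r} p(r′)` over achieved recall levels (all-point
interpolation, the exact discrete realization of the ∫p(r)dr
definition; 11-point sampling would change third-decimal values, and
the interpolation choice is recorded in every report). mAP averages
classes that have ground truth; absent classes are excluded rather than
scored zero, so a recording without drinking events is not penalized.
AP is computed on the full ranked list: truncating at the deployment
confidence threshold would cap recall below 1. The implementation is
cross-checked against a brute-force threshold-enumeration oracle to
1e-12 on randomized micro-instances.

## Behavior indices and statistics

`BI = (Σ_k OBF_k)/N` with `OBF_k` the **count** of pigs showing the
behavior in frame k (a 0/1 indicator is selectable via
`occurrence="indicator"`; the count is the default because group-level
indices above 1 — e.g. eight pigs lying — are meaningful and observed).
`N` is the declared window length including empty frames, which gives
the exact rescaling identity `BI(N+M) = BI(N)·N/(N+M)` when M empty
frames are appended. Indices are computed from post-penalization,
post-threshold detections. The analysis window and day list are
configurable; the pipeline default is days 2, 4, 6 with the full
observation window per day.

Treatment summaries report n, mean, Q1, median, Q3 per treatment × day ×
behavior using median-inclusive linear-interpolation quartiles (type 7,
numpy's default), noted in the output metadata. Correlations are plain
Pearson coefficients with explicit preconditions (n ≥ 3, non-zero
variance). Mixed-model inference on the indices is intentionally out of
scope — it is routine general-purpose statistics, not part of this
package's contribution.

## Pipeline and reproducibility

Every stochastic operation is a pure function of (inputs, seed). The
pipeline derives per-(pen, day, stage) seeds from the master seed via
CRC32 hashing (all below 2³¹), records them in the run manifest, and
writes all outputs deterministically — a rerun with the same
configuration is byte-identical. Stages run in fixed order
(simulate → detect → penalize → evaluate → index); disabling a stage
stops everything downstream.

## Problem sizes used in the validation suite

The test suite and acceptance script size their simulations to what the
statistics require: stationary-law convergence uses 12,000 frames of a
2-pig pen (contention-free, visibility threshold 0 so occlusion cannot
bias counts) with a dwell-time autocorrelation correction on the
standard errors; treatment-multiplier recovery uses the full study-shaped
design (6 pens/arm × 3 days × 720 frames) across independent seeds (20
in the test suite, 12 in the acceptance script) and asserts the median
recovered ratio within ±15% of the configured 1.5× — the band accommodates
the drinker-contention compression derived above; oracle
equivalence uses 1,000 randomized micro-instances at tolerance 1e-12.

## Known limitations

- The baseline detector merges overlapping pigs; it is a validation
  vehicle, not a usable pig detector.
- The simulator's independence assumptions (between pigs, across
  frames) understate real behavioral correlation; cross-behavior index
  correlations in simulated data are therefore near zero by design and
  carry no biological meaning.
- Penalization cannot recover drinking events missed by a detector; it
  only removes spatial false positives.
- Infrared rendering is a grayscale restyle, not a thermal model.
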