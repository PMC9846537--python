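"""IoU, detection matching, PR curves, AP and mAP."""

import numpy as np
import pytest

from penquant import (
    AnnotatedInstance,
    AnnotationCategory,
    BBox,
    Detection,
    DetectionClass,
    MatchResult,
    PRCurve,
    average_precision,
    evaluate_detections,
    iou,
    match_detections,
    mean_ap,
    plot_pr,
    pr_curve,
)
from conftest import detections_from_truth, make_frame, random_box
from _oracles import ap_bruteforce


class TestIoU:
    def test_identical_boxes(self):
        b = BBox(3, 4, 10, 20)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BBox(0, 0, 10, 10), BBox(20, 20, 30, 30)) == 0.0

    def test_partial_overlap_exact_value(self):
        # intersection 25, union 100 + 100 - 25 = 175
        assert iou(BBox(0, 0, 10, 10), BBox(5, 5, 15, 15)) == pytest.approx(25 / 175)

    def test_symmetry(self):
        a, b = BBox(0, 0, 10, 10), BBox(2, 3, 12, 9)
        assert iou(a, b) == iou(b, a)


def _truth_frame(boxes, category=AnnotationCategory.STANDING, frame_index=0):
    return make_frame(
        [AnnotatedInstance(box=b, category=category) for b in boxes], frame_index=frame_index
    )


class TestMatching:
    def test_perfect_detections_are_all_tp(self):
        frames = [_truth_frame([BBox(0, 0, 10, 10), BBox(30, 30, 50, 60)])]
        dets = detections_from_truth(frames)
        m = match_detections(dets, frames, DetectionClass.STANDING)
        assert m.flags == (True, True)
        assert m.n_false_positive == 0

    def test_duplicate_detection_on_one_box_is_fp(self):
        """Brute force over the two-detection permutation: the higher-ranked
        one takes the box, the duplicate becomes a false positive."""
        frames = [_truth_frame([BBox(0, 0, 10, 10)])]
        d_hi = Detection(box=BBox(0, 0, 10, 10), detection_class=DetectionClass.STANDING,
                         confidence=0.9)
        d_lo = Detection(box=BBox(1, 1, 11, 11), detection_class=DetectionClass.STANDING,
                         confidence=0.8)
        for order in ([d_hi, d_lo], [d_lo, d_hi]):
            m = match_detections({0: order}, frames, DetectionClass.STANDING)
            assert m.flags == (True, False)
            assert m.confidences == (0.9, 0.8)

    def test_wrong_class_over_correct_box_is_fp(self):
        frames = [_truth_frame([BBox(0, 0, 10, 10)], AnnotationCategory.STANDING)]
        det = Detection(box=BBox(0, 0, 10, 10), detection_class=DetectionClass.DRINKING,
                        confidence=0.9)
        m_drink = match_detections({0: [det]}, frames, DetectionClass.DRINKING)
        assert m_drink.flags == (False,)
        assert m_drink.n_ground_truth == 0

    def test_below_iou_threshold_is_fp(self):
        frames = [_truth_frame([BBox(0, 0, 10, 10)])]
        det = Detection(box=BBox(8, 8, 18, 18), detection_class=DetectionClass.STANDING,
                        confidence=1.0)
        m = match_detections({0: [det]}, frames, DetectionClass.STANDING)
        assert m.flags == (False,)

    def test_unknown_frame_index_raises(self):
        frames = [_truth_frame([BBox(0, 0, 10, 10)])]
        dets = {5: [Detection(box=BBox(0, 0, 10, 10),
                              detection_class=DetectionClass.STANDING, confidence=1.0)]}
        with pytest.raises(KeyError):
            match_detections(dets, frames, DetectionClass.STANDING)

    def test_tp_count_bounded_by_ground_truth(self):
        rng = np.random.default_rng(2)
        frames = [_truth_frame([random_box(rng) for _ in range(3)])]
        dets = {0: [Detection(box=random_box(rng), detection_class=DetectionClass.STANDING,
                              confidence=float(rng.random())) for _ in range(10)]}
        m = match_detections(dets, frames, DetectionClass.STANDING)
        assert m.n_true_positive <= min(10, m.n_ground_truth)


def _match(flags, n_gt, cls=DetectionClass.STANDING):
    confs = tuple(np.linspace(1.0, 0.5, len(flags)))
    return MatchResult(detection_class=cls, flags=tuple(flags), confidences=confs,
                       n_ground_truth=n_gt, iou_threshold=0.5)


class TestPRCurveAndAP:
    def test_all_tp_curve(self):
        curve = pr_curve(_match([True] * 4, 4))
        assert all(p == 1.0 for p in curve.precisions)
        assert curve.recalls[-1] == 1.0

    def test_tp_fp_tp_running_ratios(self):
        curve = pr_curve(_match([True, False, True], 2))
        assert curve.recalls == (0.5, 0.5, 1.0)
        assert curve.precisions == (1.0, 0.5, pytest.approx(2 / 3))

    def test_all_fp_curve_has_zero_precision(self):
        curve = pr_curve(_match([False, False], 3))
        assert all(p == 0.0 for p in curve.precisions)

    def test_zero_ground_truth_raises(self):
        with pytest.raises(ValueError, match="recall"):
            pr_curve(_match([True], 0))

    def test_perfect_detector_ap_is_one(self):
        assert average_precision(pr_curve(_match([True] * 5, 5))) == 1.0

    def test_all_fp_ap_is_zero(self):
        assert average_precision(pr_curve(_match([False] * 5, 5))) == 0.0

    def test_envelope_integral_hand_value(self):
        # 0.5*1.0 + 0.5*(2/3) = 5/6
        ap = average_precision(pr_curve(_match([True, False, True], 2)))
        assert ap == pytest.approx(5 / 6, abs=1e-12)

    def test_missed_boxes_cap_recall_and_ap(self):
        ap = average_precision(pr_curve(_match([True, True], 4)))
        assert ap == pytest.approx(0.5)

    def test_ap_equals_bruteforce_oracle_on_random_rankings(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_gt = int(rng.integers(1, 7))
            n_det = int(rng.integers(0, 11))
            max_tp = min(n_gt, n_det)
            flags = [bool(rng.random() < 0.5) for _ in range(n_det)]
            while sum(flags) > max_tp:
                flags[flags.index(True)] = False
            ap = average_precision(pr_curve(_match(flags, n_gt))) if n_det else 0.0
            oracle = ap_bruteforce(flags, n_gt)
            assert ap == pytest.approx(oracle, abs=1e-12)

    def test_recall_must_be_non_decreasing(self):
        with pytest.raises(ValueError):
            PRCurve(detection_class=DetectionClass.STANDING,
                    recalls=(0.5, 0.3), precisions=(1.0, 1.0))


class TestMeanAP:
    def test_reference_per_class_values(self):
        """Mean of the four per-class AP50s: feeding 0.96, drinking 0.70,
        standing 0.85, non-standing 0.86."""
        per_class = {
            DetectionClass.FEEDING: 0.96,
            DetectionClass.DRINKING: 0.70,
            DetectionClass.STANDING: 0.85,
            DetectionClass.NON_STANDING: 0.86,
        }
        assert mean_ap(per_class) == pytest.approx(0.8425, abs=1e-12)

    def test_single_class_is_identity(self):
        assert mean_ap({DetectionClass.DRINKING: 0.7}) == 0.7

    def test_all_perfect_classes(self):
        assert mean_ap({c: 1.0 for c in DetectionClass}) == 1.0

    def test_empty_mapping_raises(self):
        with pytest.raises(ValueError):
            mean_ap({})

    def test_mean_within_class_bounds(self):
        rng = np.random.default_rng(4)
        aps = {c: float(rng.random()) for c in DetectionClass}
        m = mean_ap(aps)
        assert min(aps.values()) <= m <= max(aps.values())


class TestEvaluateAndPlot:
    def test_classes_without_ground_truth_excluded(self):
        frames = [_truth_frame([BBox(0, 0, 10, 10)], AnnotationCategory.STANDING)]
        ap, curves, _ = evaluate_detections(detections_from_truth(frames), frames)
        assert set(ap.per_class) == {DetectionClass.STANDING}
        assert ap.mean == 1.0

    def test_plot_writes_file(self, tmp_path):
        curve = pr_curve(_match([True, False, True], 2))
        out = tmp_path / "pr.png"
        plot_pr([curve], out)
        assert out.stat().st_size > 0

    def test_plot_empty_input_raises(self, tmp_path):
        with pytest.raises(ValueError):
            plot_pr([], tmp_path / "x.png")


class TestNoiseAndPenalizationEffects:
    """Directional checks on simulated recordings."""

    def _median_map(self, geometry, miss, fp, n_seeds=20):
        from penquant import DetectionNoise, SimConfig, perturb_to_detections, simulate_pen

        aps = []
        for seed in range(n_seeds):
            frames = simulate_pen(SimConfig(duration=400.0, seed=seed), geometry)
            noise = DetectionNoise(localization_sd=2.0, miss_rate=miss,
                                   false_positive_rate=fp, confidence_sd=0.05)
            dets = dict(perturb_to_detections(frames, noise, seed + 100))
            ap, _, _ = evaluate_detections(dets, frames)
            aps.append(ap.mean)
        return float(np.median(aps))

    def test_more_detector_noise_never_raises_median_map(self, geometry):
        clean = self._median_map(geometry, miss=0.02, fp=0.05)
        noisy = self._median_map(geometry, miss=0.3, fp=1.0)
        assert noisy <= clean

    def test_penalization_restores_drinking_ap(self, geometry):
        """Off-zone drinking false positives lower the drinking AP; the
        spatial penalizer removes them and restores it."""
        from penquant import (DetectionNoise, SimConfig, penalize,
                              perturb_to_detections, simulate_pen)

        frames = simulate_pen(SimConfig(duration=2000.0, seed=13), geometry)
        noise = DetectionNoise(localization_sd=2.0, confidence_sd=0.03)
        dets = dict(perturb_to_detections(frames, noise, seed=0))
        rng = np.random.default_rng(1)
        for fi in list(dets)[::3]:
            x0, y0 = rng.uniform(40, 300), rng.uniform(80, 160)
            dets[fi] = dets[fi] + [
                Detection(box=BBox(x0, y0, x0 + 100, y0 + 40),
                          detection_class=DetectionClass.DRINKING,
                          confidence=float(rng.uniform(0.8, 1.0)))
            ]
        before, _, _ = evaluate_detections(dets, frames)
        penalized = {fi: penalize(d, geometry) for fi, d in dets.items()}
        after, _, _ = evaluate_detections(penalized, frames)
        assert before.per_class[DetectionClass.DRINKING] < after.per_class[DetectionClass.DRINKING]
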