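"""Pen simulator: behavior chain, placement, occlusion, noise model."""

from dataclasses import replace

import numpy as np
import pytest

from penquant import (
    AnnotationCategory,
    DetectionClass,
    DetectionNoise,
    SimConfig,
    SimulationError,
    default_geometry,
    perturb_to_detections,
    render_frame,
    simulate_pen,
    write_annotations,
)
from penquant.simulator import DEFAULT_ENTRY_WEIGHTS, DEFAULT_STAY, visible_fractions


class TestConfig:
    def test_transition_matrix_rows_sum_to_one(self):
        P = SimConfig().transition_matrix()
        assert P.shape == (6, 6)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_treatment_multiplier_scales_entry_column(self):
        base = SimConfig().transition_matrix()
        boosted = SimConfig(treatment_multipliers={"drinking": 2.0}).transition_matrix()
        i = list(AnnotationCategory).index(AnnotationCategory.DRINKING)
        j = list(AnnotationCategory).index(AnnotationCategory.STANDING)
        # entry into drinking from a different state grows, others shrink slightly
        assert boosted[j, i] > base[j, i]
        np.testing.assert_allclose(boosted.sum(axis=1), 1.0)

    def test_invalid_stay_probability_rejected(self):
        bad = dict(DEFAULT_STAY)
        bad[AnnotationCategory.STANDING] = 1.0
        with pytest.raises(SimulationError):
            SimConfig(stay_probabilities=bad).transition_matrix()

    @pytest.mark.parametrize("kwargs", [
        {"n_pigs": 0}, {"frame_rate": 0.0}, {"duration": -1.0},
        {"treatment_multipliers": {"drinking": 0.0}},
        {"treatment_multipliers": {"sleeping": 1.5}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimConfig(**kwargs)

    def test_stationary_matches_eigenvector(self):
        cfg = SimConfig(treatment_multipliers={"drinking": 1.5})
        P = cfg.transition_matrix()
        evals, evecs = np.linalg.eig(P.T)
        v = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        v = v / v.sum()
        np.testing.assert_allclose(cfg.stationary_distribution(), v, atol=1e-10)


class TestSimulatePen:
    def test_frame_count_is_floor_of_duration_times_rate(self, geometry):
        assert len(simulate_pen(SimConfig(duration=14400.0, frame_rate=0.05, seed=0,
                                          n_pigs=2), geometry)) == 720
        assert len(simulate_pen(SimConfig(duration=59.0, frame_rate=0.05, seed=0,
                                          n_pigs=2), geometry)) == 2

    def test_zero_drinking_entry_weight_means_no_drinking(self, geometry):
        weights = dict(DEFAULT_ENTRY_WEIGHTS)
        weights[AnnotationCategory.DRINKING] = 0.0
        frames = simulate_pen(SimConfig(duration=2000.0, seed=2, entry_weights=weights), geometry)
        assert not any(
            i.category is AnnotationCategory.DRINKING for f in frames for i in f.instances
        )

    def test_same_seed_gives_byte_identical_files(self, tmp_path, geometry):
        cfg = SimConfig(duration=400.0, seed=11)
        for name in ("a.csv", "b.csv"):
            write_annotations(simulate_pen(cfg, geometry), tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        write_annotations(simulate_pen(replace(cfg, seed=12), geometry), tmp_path / "c.csv")
        assert (tmp_path / "a.csv").read_bytes() != (tmp_path / "c.csv").read_bytes()

    def test_drinking_and_feeding_centers_inside_their_zones(self, geometry):
        frames = simulate_pen(SimConfig(duration=4000.0, seed=3), geometry)
        n_drink = n_feed = 0
        for f in frames:
            for inst in f.instances:
                cx, cy = inst.box.center
                if inst.category is AnnotationCategory.DRINKING:
                    n_drink += 1
                    assert any(z.contains_point(cx, cy) for z in geometry.drinker_zones)
                elif inst.category is AnnotationCategory.FEEDING:
                    n_feed += 1
                    assert any(z.contains_point(cx, cy) for z in geometry.feeder_zones)
        assert n_drink > 0 and n_feed > 0  # the check must have bite

    def test_single_drinker_admits_at_most_one_pig_per_frame(self, geometry):
        frames = simulate_pen(SimConfig(duration=4000.0, seed=4), geometry)
        for f in frames:
            assert sum(1 for i in f.instances if i.category is AnnotationCategory.DRINKING) <= 1

    def test_each_pig_labeled_once_and_visibility_respected(self, geometry):
        cfg = SimConfig(duration=1000.0, seed=5)
        for f in simulate_pen(cfg, geometry):
            ids = [i.pig_id for i in f.instances]
            assert len(ids) == len(set(ids))
            assert len(ids) <= cfg.n_pigs
            assert all(i.visible_fraction >= cfg.visibility_threshold for i in f.instances)

    def test_empirical_fractions_converge_to_stationary(self, geometry):
        """Long-horizon behavior fractions match the chain's stationary law.

        Two pigs keep resource contention negligible; visibility threshold
        0 so occlusion dropping cannot bias the counts. Tolerance is 3
        standard errors with an autocorrelation (dwell-time) correction.
        """
        cfg = SimConfig(
            n_pigs=2, duration=240000.0, seed=6, visibility_threshold=0.0
        )  # 12,000 frames
        frames = simulate_pen(cfg, geometry)
        counts = {c: 0 for c in AnnotationCategory}
        total = 0
        for f in frames:
            for inst in f.instances:
                counts[inst.category] += 1
                total += 1
        pi = cfg.stationary_distribution()
        for i, cat in enumerate(AnnotationCategory):
            emp = counts[cat] / total
            s = cfg.stay_probabilities[cat]
            tau = (1 + s) / (1 - s)  # integrated autocorrelation of a sticky state
            se = np.sqrt(pi[i] * (1 - pi[i]) * tau / total)
            assert abs(emp - pi[i]) < 3 * se, f"{cat}: emp={emp:.4f} pi={pi[i]:.4f} se={se:.4f}"

    def test_treatment_multiplier_monotonically_increases_drinking(self, geometry):
        """Expected drinking occupancy strictly rises with the entry multiplier."""
        totals = {}
        for m in (1.0, 2.0):
            n = 0
            for seed in range(20):
                cfg = SimConfig(
                    duration=2000.0, seed=seed, treatment_multipliers={"drinking": m}
                )
                n += sum(
                    1
                    for f in simulate_pen(cfg, geometry)
                    for i in f.instances
                    if i.category is AnnotationCategory.DRINKING
                )
            totals[m] = n
        assert totals[2.0] > totals[1.0]


class TestOcclusion:
    def test_half_overlap_gives_half_visibility(self):
        boxes = np.array([[0, 0, 10, 10], [5, 0, 15, 10]], dtype=float)
        vis = visible_fractions(boxes)
        assert vis[0] == pytest.approx(0.5)
        assert vis[1] == 1.0

    def test_overlapping_occluders_not_double_counted(self):
        boxes = np.array(
            [[0, 0, 10, 10], [4, 0, 14, 10], [6, 0, 16, 10]], dtype=float
        )
        vis = visible_fractions(boxes)
        # union of [4,10] and [6,10] strips covers x in [4,10]: 60 of 100
        assert vis[0] == pytest.approx(0.4)
        # box 1 occluded by box 2 over x in [6,14]: 80 of 100
        assert vis[1] == pytest.approx(0.2)
        assert vis[2] == 1.0

    def test_disjoint_boxes_fully_visible(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30]], dtype=float)
        np.testing.assert_allclose(visible_fractions(boxes), 1.0)


class TestRenderFrame:
    def test_empty_frame_renders_background_only(self, geometry):
        from conftest import make_frame
        from penquant import baseline_blob_detector

        img = render_frame(make_frame([]), geometry, "rgb")
        assert img.ndim == 3 and img.shape[2] == 3 and img.dtype == np.uint8
        assert baseline_blob_detector(img, geometry) == []

    def test_infrared_is_single_channel(self, geometry):
        from conftest import make_frame

        img = render_frame(make_frame([]), geometry, "infrared")
        assert img.ndim == 2 and img.dtype == np.uint8


class TestPerturbToDetections:
    @pytest.fixture
    def frames(self, geometry):
        return simulate_pen(SimConfig(duration=2000.0, seed=7), geometry)  # 100 frames

    def test_identity_noise_reproduces_truth_with_confidence_one(self, frames):
        out = perturb_to_detections(frames, DetectionNoise.identity(), seed=0)
        assert len(out) == len(frames)
        for (fi, dets), fr in zip(out, frames):
            assert fi == fr.frame_index
            assert len(dets) == len(fr.instances)
            for det, inst in zip(dets, fr.instances):
                assert det.box == inst.box
                assert det.confidence == 1.0
                assert det.detection_class == inst.detection_class

    def test_total_miss_rate_yields_no_detections(self, frames):
        out = perturb_to_detections(frames, DetectionNoise(miss_rate=1.0), seed=0)
        assert all(dets == [] for _, dets in out)

    def test_survivors_within_three_binomial_sd(self, frames):
        n_instances = sum(len(f.instances) for f in frames)
        miss = 0.2
        out = perturb_to_detections(frames, DetectionNoise(miss_rate=miss), seed=42)
        survivors = sum(len(d) for _, d in out)
        expected = n_instances * (1 - miss)
        sd = np.sqrt(n_instances * miss * (1 - miss))
        assert abs(survivors - expected) < 3 * sd

    def test_deterministic_given_seed(self, frames):
        noise = DetectionNoise(localization_sd=3.0, miss_rate=0.1, false_positive_rate=0.3,
                               confidence_sd=0.05)
        a = perturb_to_detections(frames, noise, seed=9)
        b = perturb_to_detections(frames, noise, seed=9)
        assert a == b

    def test_false_positive_rate_adds_poisson_spurious_boxes(self, frames):
        rate = 0.5
        out = perturb_to_detections(
            frames, DetectionNoise(miss_rate=1.0, false_positive_rate=rate), seed=3
        )
        n_fp = sum(len(d) for _, d in out)
        lam = rate * len(frames)
        assert abs(n_fp - lam) < 3 * np.sqrt(lam)

    def test_confusion_row_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="confusion"):
            DetectionNoise(
                confusion={
                    DetectionClass.STANDING: {
                        DetectionClass.STANDING: 0.5,
                        DetectionClass.NON_STANDING: 0.4,
                    }
                }
            )

    def test_class_confusion_applied_at_expected_rate(self, frames):
        noise = DetectionNoise(
            confusion={
                DetectionClass.STANDING: {
                    DetectionClass.STANDING: 0.7,
                    DetectionClass.NON_STANDING: 0.3,
                }
            }
        )
        out = perturb_to_detections(frames, noise, seed=5)
        n_standing_true = sum(
            1 for f in frames for i in f.instances if i.detection_class is DetectionClass.STANDING
        )
        n_standing_pred = sum(
            1 for (fi, dets) in out for d in dets if d.detection_class is DetectionClass.STANDING
        )
        flips = n_standing_true - n_standing_pred
        sd = np.sqrt(n_standing_true * 0.3 * 0.7)
        assert abs(flips - 0.3 * n_standing_true) < 3 * sd
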