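"""Digital fixation / saccade segmentation against hand counts and a
brute-force label-then-scan oracle."""

import numpy as np
import pytest

from digitrace import (ScreenGeometry, SpeedThreshold, compute_speeds,
                       median_speed_threshold, segment, threshold_sweep,
                       trial_kinematics)
from digitrace.event_segmentation import SpeedSeries

from conftest import make_trajectory
from oracle_segmentation import brute_force_segment


def px_for_speed(speed_mm_s, geometry):
    """Per-frame x-displacement in px producing a given speed."""
    return speed_mm_s / geometry.pixel_pitch / geometry.sampling_rate


def trajectory_from_speeds(speeds_mm_s, geometry, y_px=640.0):
    """Monotone-x trajectory whose successive speeds are as requested."""
    steps = [px_for_speed(s, geometry) for s in speeds_mm_s]
    x = np.concatenate([[500.0], 500.0 + np.cumsum(steps)])
    return make_trajectory(x, np.full(len(x), y_px), geometry)


class TestComputeSpeeds:
    def test_pythagorean_displacement(self, geometry):
        # (0,0) -> (3,4) px in one frame: 5 px * pitch / dt
        tr = make_trajectory([0.0, 3.0], [0.0, 4.0], geometry)
        s = compute_speeds(tr, geometry)
        expected = 5.0 * geometry.pixel_pitch * geometry.sampling_rate
        assert s.values == pytest.approx([expected])

    def test_known_pitch_gives_40_5(self):
        geom = ScreenGeometry(pixel_pitch=0.135)
        tr = make_trajectory([0.0, 3.0], [0.0, 4.0], geom)
        assert compute_speeds(tr, geom).values == pytest.approx([40.5])

    def test_stationary_finger_zero(self, geometry):
        tr = make_trajectory([100.0] * 5, [100.0] * 5, geometry)
        assert np.all(compute_speeds(tr, geometry).values == 0)

    def test_counting_n_minus_one(self, geometry, rng):
        x = 500 + np.cumsum(rng.uniform(0, 2, size=17))
        tr = make_trajectory(x, np.full(17, 600.0), geometry)
        assert len(compute_speeds(tr, geometry).values) == 16

    def test_touch_gap_yields_nan(self, geometry):
        tr = make_trajectory([0, 1, 2, 3], [0, 0, 0, 0], geometry,
                             touching=[True, True, False, True])
        v = compute_speeds(tr, geometry).values
        assert np.isfinite(v[0]) and np.isnan(v[1]) and np.isnan(v[2])

    def test_single_sample_warns_empty(self, geometry):
        tr = make_trajectory([0.0], [0.0], geometry)
        with pytest.warns(UserWarning):
            assert len(compute_speeds(tr, geometry).values) == 0


class TestMedianThreshold:
    def _series(self, values):
        return SpeedSeries("S1", 1, "t1", np.asarray(values, dtype=float))

    def test_nulls_excluded(self):
        thr = median_speed_threshold(self._series([0, 0, 1, 2, 3, 4, 5]))
        assert thr.value == 3

    def test_even_count_midpoint(self):
        assert median_speed_threshold(self._series([1, 2, 3, 4])).value == 2.5

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_speed_threshold(self._series([0.0, 0.0]))

    def test_pooled_across_trials(self):
        thr = median_speed_threshold([self._series([1, 2]),
                                      self._series([3, 4, 5])])
        assert thr.value == 3

    def test_mixed_subjects_rejected(self):
        a = SpeedSeries("S1", 1, "t1", np.array([1.0]))
        b = SpeedSeries("S2", 1, "t1", np.array([2.0]))
        with pytest.raises(ValueError):
            median_speed_threshold([a, b])

    @pytest.mark.parametrize("n", [5, 8, 13])
    def test_matches_sort_and_pick_oracle(self, rng, n):
        vals = np.round(rng.uniform(0, 10, size=n), 3)
        vals[rng.random(n) < 0.3] = 0.0
        pos = sorted(v for v in vals if v > 0)
        if not pos:
            return
        k = len(pos)
        expect = pos[k // 2] if k % 2 else (pos[k // 2 - 1] + pos[k // 2]) / 2
        assert median_speed_threshold(self._series(vals)).value == pytest.approx(expect)


class TestSegment:
    def test_streak_enumeration(self, geometry):
        tr = trajectory_from_speeds([1, 1, 9, 9, 1, 1], geometry)
        thr = SpeedThreshold("S1", 1, 3.0)
        fx, sc = segment(tr, thr, geometry)
        # 7 samples; the first carries no speed and joins the slow streak
        assert [f.n_samples for f in fx] == [3, 2]
        assert [s.n_samples for s in sc] == [2]
        assert sc[0].from_fixation == 0 and sc[0].to_fixation == 1

    def test_all_slow_single_fixation(self, geometry):
        tr = trajectory_from_speeds([1, 1, 1, 1], geometry)
        fx, sc = segment(tr, SpeedThreshold("S1", 1, 3.0), geometry)
        assert len(fx) == 1 and len(sc) == 0

    def test_equal_endpoints_regressive(self, geometry):
        # fast out-and-back: saccade's first and last x coincide
        x = [500, 500, 520, 500, 500]
        tr = make_trajectory(x, [600] * 5, geometry)
        fx, sc = segment(tr, SpeedThreshold("S1", 1, 3.0), geometry)
        assert len(sc) == 1
        assert sc[0].direction == "regressive"

    def test_drifting_slow_streak_splits(self, geometry):
        # 20 px drift at ~1 px/frame is slow but violates the 5.8 px X limit
        x = 500 + np.arange(21) * 1.0
        tr = make_trajectory(x, np.full(21, 600.0), geometry)
        thr_value = 2.0 * geometry.pixel_pitch * geometry.sampling_rate
        fx, sc = segment(tr, SpeedThreshold("S1", 1, thr_value), geometry)
        assert len(fx) >= 2
        assert len(sc) == 0
        for f in fx:
            xs = x[list(f.sample_indices)]
            assert xs.max() - xs.min() < 5.8

    def test_at_threshold_joins_slow_class(self, geometry):
        tr = trajectory_from_speeds([5.0, 5.0], geometry)
        # use the exact measured value so the comparison is bitwise at-threshold
        exact = float(compute_speeds(tr, geometry).values.max())
        fx, sc = segment(tr, SpeedThreshold("S1", 1, exact), geometry)
        assert len(fx) == 1 and len(sc) == 0

    def test_conservation_of_samples(self, geometry, rng):
        for _ in range(20):
            n = rng.integers(2, 50)
            x = 500 + np.cumsum(rng.uniform(0, 6, size=n))
            touching = rng.random(n) > 0.1
            tr = make_trajectory(x, np.full(n, 600.0), geometry,
                                 touching=touching)
            fx, sc = segment(tr, SpeedThreshold("S1", 1, 10.0), geometry)
            counted = sum(f.n_samples for f in fx) + sum(s.n_samples for s in sc)
            assert counted + int((~touching).sum()) == n

    def test_events_time_ordered_non_overlapping(self, geometry, rng):
        x = 500 + np.cumsum(rng.uniform(0, 8, size=40))
        tr = make_trajectory(x, np.full(40, 600.0), geometry)
        fx, sc = segment(tr, SpeedThreshold("S1", 1, 12.0), geometry)
        spans = sorted([(f.start_t, f.end_t) for f in fx]
                       + [(s.start_t, s.end_t) for s in sc])
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 < b0 or (a1 <= b0)  # ends never pass the next start
            assert a0 <= a1 and b0 <= b1

    def test_unit_invariance_of_thresholding(self, geometry, rng):
        """Median thresholding is invariant to a monotone unit change:
        scaling the pixel pitch rescales speeds and threshold alike."""
        x = 500 + np.cumsum(rng.uniform(0, 6, size=30))
        y = 600 + np.cumsum(rng.uniform(-1, 1, size=30))
        g2 = ScreenGeometry(pixel_pitch=geometry.pixel_pitch * 7.3)
        tr1 = make_trajectory(x, y, geometry)
        tr2 = make_trajectory(x, y, g2)
        t1 = median_speed_threshold(compute_speeds(tr1, geometry))
        t2 = median_speed_threshold(compute_speeds(tr2, g2))
        fx1, sc1 = segment(tr1, t1, geometry)
        fx2, sc2 = segment(tr2, t2, g2)
        assert [f.sample_indices for f in fx1] == [f.sample_indices for f in fx2]
        assert [s.sample_indices for s in sc1] == [s.sample_indices for s in sc2]

    def test_matches_brute_force_oracle_random(self, geometry, rng):
        """Production segmentation equals the label-then-scan classifier on
        random short trajectories (the full 1000-trajectory sweep runs in
        the acceptance suite)."""
        for _ in range(100):
            n = int(rng.integers(2, 51))
            x = 500 + np.cumsum(rng.uniform(-4, 8, size=n))
            y = 600 + np.cumsum(rng.uniform(-3, 3, size=n))
            touching = rng.random(n) > 0.15
            tr = make_trajectory(x, y, geometry, touching=touching)
            thr_val = float(rng.uniform(2, 25))
            fx, sc = segment(tr, SpeedThreshold("S1", 1, thr_val), geometry)
            ofx, osc = brute_force_segment(tr, thr_val, geometry)
            assert [f.sample_indices for f in fx] == [o["indices"] for o in ofx]
            assert [s.sample_indices for s in sc] == [o["indices"] for o in osc]
            for f, o in zip(fx, ofx):
                assert f.barycenter_x == pytest.approx(o["bary_x"])
            for s, o in zip(sc, osc):
                assert s.direction == o["direction"]
                assert (np.isnan(s.length) and np.isnan(o["length"])) or \
                    s.length == pytest.approx(o["length"])


class TestTrialKinematics:
    def test_regressive_ratio(self, geometry):
        x = [500]
        # build 8 saccades, 2 of them regressive, via alternating speeds
        tr = trajectory_from_speeds([1, 1], geometry)
        fx, sc = segment(tr, SpeedThreshold("S1", 1, 3.0), geometry)
        kin = trial_kinematics(fx, sc)
        assert kin.n_saccades == 0 and np.isnan(kin.proportion_regressive)

    def test_proportion_from_counts(self, geometry, rng):
        # zig-zag with 8 two-sample fast jumps, 2 of them leftward
        jumps = [30, 30, 30, -30, 30, 30, -30, 30]
        xs = [500.0]
        for j in jumps:
            xs.append(xs[-1] + 1)                    # slow pair
            xs.append(xs[-1] + 1)
            xs.append(xs[-1] + j)                    # fast jump, 2 samples
            xs.append(xs[-1] + j)
        xs.append(xs[-1] + 1)
        xs.append(xs[-1] + 1)
        tr = make_trajectory(np.array(xs), np.full(len(xs), 600.0), geometry)
        thr = 10 * geometry.pixel_pitch * geometry.sampling_rate
        fx, sc = segment(tr, SpeedThreshold("S1", 1, thr), geometry)
        kin = trial_kinematics(fx, sc)
        assert kin.n_saccades == 8
        assert kin.n_regressive == 2
        assert kin.proportion_regressive == pytest.approx(0.25)

    def test_mean_duration(self, geometry):
        from digitrace.event_segmentation import DigitalFixation

        f1 = DigitalFixation(0, 100, 0, 0, 7)
        f2 = DigitalFixation(200, 500, 0, 0, 19)
        kin = trial_kinematics([f1, f2], [])
        assert kin.mean_fixation_duration == pytest.approx(200.0)


class TestThresholdSweep:
    def test_consistency_with_segment(self, geometry, rng):
        x = 500 + np.cumsum(rng.uniform(0, 6, size=30))
        tr = make_trajectory(x, np.full(30, 600.0), geometry)
        med = median_speed_threshold(compute_speeds(tr, geometry))
        sweep = threshold_sweep(tr, [med.value], geometry)
        fx, _ = segment(tr, med, geometry)
        assert sweep[med.value] == len(fx)

    def test_threshold_below_all_speeds_no_fixation(self, geometry):
        tr = trajectory_from_speeds([20, 25, 30], geometry)
        sweep = threshold_sweep(tr, [1.0], geometry)
        assert sweep[1.0] == 0

    def test_two_regime_argmax_between_regimes(self, geometry, rng):
        """On a slow-jitter + fast-jump trace the fixation count is
        maximised by thresholds separating the regimes."""
        xs = []
        for k in range(12):
            center = 500.0 + 4.0 * k        # 4 px apart: fast but mergeable
            for i in range(8):              # 0.8 px jitter steps
                xs.append(center + (0.4 if i % 2 == 0 else -0.4))
        x = np.array(xs)
        tr = make_trajectory(x, np.full(len(x), 600.0), geometry)
        to_mm_s = geometry.pixel_pitch * geometry.sampling_rate
        # below the jitter regime / between regimes / above the jump regime
        candidates = np.array([0.1, 2.0, 60.0]) * to_mm_s
        sweep = threshold_sweep(tr, list(candidates), geometry)
        counts = [sweep[c] for c in candidates]
        assert counts[1] == 12          # one fixation per jitter cluster
        assert counts[1] > counts[0]    # everything fast: no fixations
        assert counts[1] > counts[2]    # everything slow: clusters merge

    def test_empty_candidates_error(self, geometry):
        tr = trajectory_from_speeds([1, 2], geometry)
        with pytest.raises(ValueError):
            threshold_sweep(tr, [], geometry)
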