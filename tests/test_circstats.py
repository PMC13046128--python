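"""Circular descriptives and inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordpolar import circstats as cs


def circ_diff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


def grid_median_objective(angles, phi_deg):
    """Mean arc distance (radians) from the sample to phi, written plainly."""
    a = np.deg2rad(np.asarray(angles))
    p = np.deg2rad(phi_deg)
    d = np.abs(a - p) % (2 * np.pi)
    return float(np.mean(np.pi - np.abs(np.pi - d)))


class TestDescriptives:
    def test_mean_symmetric_about_zero(self):
        assert circ_diff(cs.circular_mean([10.0, 350.0]), 0.0) < 1e-9

    def test_mean_single_and_pair(self):
        assert cs.circular_mean([90.0]) == pytest.approx(90.0)
        assert cs.circular_mean([0.0, 90.0]) == pytest.approx(45.0)

    def test_mean_undefined_for_antipodal(self):
        with pytest.raises(cs.UndefinedMeanError):
            cs.circular_mean([0.0, 180.0])

    def test_variance_extremes(self):
        assert cs.circular_variance([33.0] * 5) == pytest.approx(0.0)
        assert cs.circular_variance([0.0, 90.0, 180.0, 270.0]) == \
            pytest.approx(1.0)
        assert cs.circular_variance([0.0, 180.0]) == pytest.approx(1.0)

    def test_median_middle_of_arc(self):
        assert cs.circular_median([10.0, 20.0, 30.0]) == pytest.approx(20.0)

    def test_median_wraps_around_zero(self):
        assert cs.circular_median([350.0, 0.0, 10.0]) == pytest.approx(0.0)

    def test_median_ambiguous_for_antipodal_data(self):
        with pytest.raises(cs.AmbiguousMedianError):
            cs.circular_median([0.0, 90.0, 180.0, 270.0])

    def test_median_matches_grid_search(self, rng):
        for _ in range(5):
            angles = np.degrees(rng.vonmises(rng.uniform(-np.pi, np.pi),
                                             1.5, 15)) % 360.0
            med = cs.circular_median(angles)
            grid = np.arange(0.0, 360.0, 0.1)
            objs = [grid_median_objective(angles, g) for g in grid]
            best = grid[int(np.argmin(objs))]
            assert grid_median_objective(angles, med) <= min(objs) + 1e-9
            assert circ_diff(med, best) <= 0.2


class TestCommonMedianTest:
    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cs.common_median_test([[1.0] * 5, [2.0] * 5])

    def test_p_close_to_permutation_oracle(self, rng):
        groups = [
            (np.degrees(rng.vonmises(0.0, 1.0, 20)) % 360.0),
            (np.degrees(rng.vonmises(0.6, 1.0, 20)) % 360.0),
            (np.degrees(rng.vonmises(-0.4, 1.0, 20)) % 360.0),
        ]
        res = cs.common_median_test(groups)
        # permutation reference: reshuffle group labels, recompute statistic
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            try:
                stat = cs.common_median_test(parts).statistic
            except cs.DegeneratePartitionError:
                continue
            if stat >= res.statistic - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert res.p_value == pytest.approx(p_perm, abs=0.05)

    def test_group_means_reported(self, rng):
        g1 = np.degrees(rng.vonmises(0.0, 3.0, 30)) % 360.0
        g2 = np.degrees(rng.vonmises(1.0, 3.0, 30)) % 360.0
        res = cs.common_median_test([g1, g2], labels=["a", "b"])
        assert set(res.group_means) == {"a", "b"}
        assert circ_diff(res.group_means["a"], 0.0) < 15.0


class TestKuiper:
    def test_identical_samples(self):
        a = np.array([10.0, 40.0, 200.0, 330.0, 355.0])
        res = cs.kuiper_two_sample(a, a.copy(), n_perm=200, seed=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        a = rng.uniform(0, 360, 40)
        b = rng.uniform(0, 360, 55)
        v0 = cs.kuiper_statistic(a, b)
        for c in (13.0, 90.0, 271.5):
            assert cs.kuiper_statistic((a + c) % 360,
                                       (b + c) % 360) == pytest.approx(v0)

    def test_detects_gross_shift(self, rng):
        a = np.degrees(rng.vonmises(0.0, 2.0, 100)) % 360.0
        b = np.degrees(rng.vonmises(np.pi / 2, 2.0, 100)) % 360.0
        res = cs.kuiper_two_sample(a, b, n_perm=999, seed=1)
        assert res.p_value < 0.01

    def test_asymptotic_close_to_permutation(self, rng):
        a = np.degrees(rng.vonmises(0.0, 1.0, 60)) % 360.0
        b = np.degrees(rng.vonmises(0.5, 1.0, 60)) % 360.0
        p_perm = cs.kuiper_two_sample(a, b, n_perm=4000, seed=2).p_value
        p_asym = cs.kuiper_two_sample(a, b, method="asymptotic").p_value
        assert p_asym == pytest.approx(p_perm, abs=0.06)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            cs.kuiper_two_sample([1.0] * 4, [2.0] * 10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert cs.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        q = cs.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_ties_all_equal(self):
        assert np.allclose(cs.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            cs.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_q_dominates_p_and_is_bounded(self, pvals):
        q = cs.bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()


class TestMeanAngleCI:
    def test_degenerate_sample_zero_width(self):
        mean, lo, hi = cs.mean_angle_ci([77.0] * 20)
        assert mean == pytest.approx(77.0)
        assert lo == pytest.approx(77.0)
        assert hi == pytest.approx(77.0)

    def test_uniform_small_sample_raises(self, rng):
        angles = rng.uniform(0, 360, 12)
        with pytest.raises(ValueError):
            cs.mean_angle_ci(angles)

    def test_coverage_near_nominal(self, rng):
        # the true mean (30 deg) should fall inside the wrapped arc
        # [lo, hi] in about 95% of replicates
        hits = 0
        reps = 300
        for _ in range(reps):
            a = np.degrees(rng.vonmises(np.deg2rad(30.0), 4.0, 200)) % 360.0
            _, lo, hi = cs.mean_angle_ci(a)
            inside = ((30.0 - lo) % 360.0) <= ((hi - lo) % 360.0)
            hits += inside
        assert 0.90 <= hits / reps <= 0.99


class TestRotationEquivariance:
    def test_statistics_rotate_with_the_data(self, rng):
        a = np.degrees(rng.vonmises(1.0, 2.0, 40)) % 360.0
        b = np.degrees(rng.vonmises(1.3, 2.0, 40)) % 360.0
        c = 123.4
        ar, br = (a + c) % 360.0, (b + c) % 360.0
        assert circ_diff(cs.circular_mean(ar),
                         (cs.circular_mean(a) + c) % 360.0) < 1e-9
        assert circ_diff(cs.circular_median(ar),
                         (cs.circular_median(a) + c) % 360.0) < 1e-6
        assert cs.circular_variance(ar) == pytest.approx(
            cs.circular_variance(a))
        assert cs.kuiper_statistic(ar, br) == pytest.approx(
            cs.kuiper_statistic(a, b))
        s0 = cs.common_median_test([a, b]).statistic
        s1 = cs.common_median_test([ar, br]).statistic
        assert s1 == pytest.approx(s0)
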