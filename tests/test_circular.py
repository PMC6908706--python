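"""Phase angles and circular statistics, cross-checked against brute force,
pingouin, and a permutation oracle."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrainkit import circular as circ


class TestToPhaseAngles:
    def test_perfect_lock_all_zero(self):
        pa = circ.to_phase_angles([0, 0.89, 1.78], 0.89)
        np.testing.assert_allclose(pa.angles, 0.0, atol=1e-9)

    def test_half_period_is_180(self):
        pa = circ.to_phase_angles([0, 1.335], 0.89)
        np.testing.assert_allclose(pa.angles, [0, 180], atol=1e-9)

    def test_linear_drift_advances_constant_angle(self):
        # each step overshoots the reference period by 0.0445 s = 18 degrees
        onsets = np.cumsum([0] + [0.89 + 0.0445] * 10)
        pa = circ.to_phase_angles(onsets, 0.89)
        np.testing.assert_allclose(pa.angles, (18 * np.arange(11)) % 360, atol=1e-6)

    def test_invariant_to_whole_period_translation(self, rng):
        onsets = np.sort(rng.uniform(0, 20, 30))
        a = circ.to_phase_angles(onsets, 0.89, t0=0.0)
        b = circ.to_phase_angles(onsets + 3 * 0.89, 0.89, t0=0.0)
        np.testing.assert_allclose(a.angles, b.angles, atol=1e-8)

    def test_first_step_anchors_zero(self, rng):
        onsets = np.sort(rng.uniform(5, 25, 20))
        assert circ.to_phase_angles(onsets, 0.89).angles[0] == 0.0

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            circ.to_phase_angles([0, 1], 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        onsets=st.lists(
            st.floats(0, 100, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=30,
        ),
        period=st.floats(0.3, 2.0),
        k=st.integers(-3, 3),
    )
    def test_period_translation_invariance_property(self, onsets, period, k):
        onsets = np.sort(np.asarray(onsets))
        a = circ.to_phase_angles(onsets, period, t0=0.0).angles
        b = circ.to_phase_angles(onsets + k * period, period, t0=0.0).angles
        assert np.all((a >= 0) & (a < 360)) and np.all((b >= 0) & (b < 360))
        diff = np.abs(a - b)
        assert np.all(np.minimum(diff, 360 - diff) < 1e-6)


class TestCircularSummary:
    def test_degenerate_concentration(self):
        s = circ.circular_summary(np.full(10, 45.0))
        assert s.mean_angle == pytest.approx(45.0)
        assert s.r_bar == pytest.approx(1.0)
        assert s.circ_sd == 0.0

    def test_symmetric_four_points_uniform(self):
        s = circ.circular_summary(np.array([0.0, 90.0, 180.0, 270.0]))
        assert s.r_bar == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_resultant(self, rng):
        angles = rng.uniform(0, 360, 200)
        s = circ.circular_summary(angles)
        # brute force: average the unit vectors one by one
        vx = sum(np.cos(np.deg2rad(a)) for a in angles) / len(angles)
        vy = sum(np.sin(np.deg2rad(a)) for a in angles) / len(angles)
        assert s.r_bar == pytest.approx(np.hypot(vx, vy), rel=1e-12)
        assert s.mean_angle == pytest.approx(np.rad2deg(np.arctan2(vy, vx)) % 360, rel=1e-9)

    def test_agrees_with_pingouin(self, rng):
        rad = rng.vonmises(1.0, 2.0, 150)
        s = circ.circular_summary(np.rad2deg(rad) % 360)
        assert s.r_bar == pytest.approx(float(pg.circ_r(rad)), rel=1e-9)
        z, p = pg.circ_rayleigh(rad)
        assert s.rayleigh_p == pytest.approx(p, rel=1e-6)

    def test_rotation_invariance(self, rng):
        angles = rng.uniform(0, 360, 100)
        s0 = circ.circular_summary(angles)
        s1 = circ.circular_summary((angles + 73.0) % 360)
        assert s1.mean_angle == pytest.approx((s0.mean_angle + 73.0) % 360, abs=1e-8)
        assert s1.r_bar == pytest.approx(s0.r_bar, rel=1e-12)
        assert s1.rayleigh_p == pytest.approx(s0.rayleigh_p, rel=1e-9)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            circ.circular_summary(np.array([10.0]))


class TestCircularAnova:
    def test_identical_groups_null(self, rng):
        g = np.rad2deg(rng.vonmises(0.5, 5.0, 40)) % 360
        res = circ.circular_anova([g, g.copy()])
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)
        assert (res.df_between, res.df_within) == (1, 78)

    def test_separated_groups_reject(self, rng):
        g1 = np.rad2deg(rng.vonmises(0.0, 20.0, 40)) % 360
        g2 = np.rad2deg(rng.vonmises(np.pi / 2, 20.0, 40)) % 360
        res = circ.circular_anova([g1, g2])
        assert res.p < 1e-3
        # the permutation oracle agrees on the rejection
        assert circ.permutation_anova_p([g1, g2], n_perm=2000, seed=1) < 0.01

    def test_low_concentration_flagged(self, rng):
        g1 = rng.uniform(0, 360, 30)
        g2 = rng.uniform(0, 360, 30)
        assert circ.circular_anova([g1, g2]).low_concentration_warning

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            circ.circular_anova([np.array([0.0, 1.0])])


class TestCircularCorrelation:
    def test_identity_is_one(self, rng):
        a = np.rad2deg(rng.vonmises(0, 2.0, 50)) % 360
        res = circ.circular_correlation(a, a, n_boot=50, seed=0)
        assert res.r_js == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-4

    def test_negated_sample_is_minus_one(self, rng):
        a = np.rad2deg(rng.vonmises(0, 2.0, 50)) % 360
        res = circ.circular_correlation(a, (-a) % 360, n_boot=50, seed=0)
        assert res.r_js == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_under_common_rotation(self, rng):
        a = np.rad2deg(rng.vonmises(0.3, 1.5, 60)) % 360
        b = np.rad2deg(rng.vonmises(1.0, 1.5, 60)) % 360
        r0 = circ.circular_correlation(a, b, n_boot=10, seed=0).r_js
        r1 = circ.circular_correlation((a + 120) % 360, b, n_boot=10, seed=0).r_js
        r2 = circ.circular_correlation(a, (b + 300) % 360, n_boot=10, seed=0).r_js
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(r0, abs=1e-9)

    def test_matches_pingouin_coefficient(self, rng):
        a = rng.vonmises(0.0, 1.0, 80)
        b = 0.8 * a + rng.normal(0, 0.4, 80)
        ours = circ.circular_correlation(np.rad2deg(a) % 360, np.rad2deg(b) % 360, n_boot=10, seed=0)
        r_pg, p_pg = pg.circ_corrcc(a, b)
        assert ours.r_js == pytest.approx(float(r_pg), rel=1e-9)
        assert ours.p == pytest.approx(float(p_pg), rel=1e-6)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        a = np.rad2deg(rng.vonmises(0, 1.0, 100)) % 360
        b = (a + np.rad2deg(rng.normal(0, 0.3, 100))) % 360
        res = circ.circular_correlation(a, b, n_boot=500, seed=7)
        lo, hi = res.ci95
        assert lo - 0.05 <= res.r_js <= hi + 0.05

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            circ.circular_correlation(np.array([0.0, 10.0]), np.array([5.0, 15.0]))
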