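"""Wind-triangle decomposition, drift regressions and circular stats."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy.stats import vonmises

from natalnav.geodesy import GeoPoint
from natalnav.trackseg import GeoFix
from natalnav.winddrift import (
    MotionVectors,
    WindField,
    WindSample,
    circ_mean_ci,
    decompose_step,
    drift_regressions,
    overcompensation_fraction,
    watson_two_sample,
)

from conftest import T0, behaviour_steps, straight_fixes


def _step(bearing, speed_kmh=50.0, hours=1.0, start=(35.0, -70.0)):
    """A fix pair realizing one groundtrack vector."""
    fixes = straight_fixes(bearing, 1, speed_kmh=speed_kmh * hours, start=start)
    a = fixes[0]
    b = GeoFix(a.timestamp + timedelta(hours=hours), fixes[1].position)
    return a, b


class TestDecomposeStep:
    def test_crosswind_from_the_left(self):
        # southbound at 50 with a 20 km/h wind toward east: no drift
        # angle, wind fully perpendicular (to the left, so negative)
        a, b = _step(180.0)
        mv = decompose_step(a, b, WindSample(20.0, 0.0), mu=180.0)
        assert mv.delta == pytest.approx(0.0, abs=1e-6)
        assert mv.p_m == pytest.approx(0.0, abs=1e-4)
        assert mv.f_m == pytest.approx(50.0, rel=1e-4)
        assert mv.t_w == pytest.approx(0.0, abs=1e-9)
        assert mv.p_w == pytest.approx(-20.0, abs=1e-9)
        assert mv.a_m == pytest.approx(50.0, rel=1e-4)
        assert mv.h_speed == pytest.approx(math.hypot(20.0, 50.0), rel=1e-4)
        assert mv.h_bearing == pytest.approx(201.8, abs=0.05)

    def test_zero_wind_heading_equals_groundtrack(self):
        a, b = _step(210.0)
        mv = decompose_step(a, b, WindSample(0.0, 0.0), mu=200.0)
        assert mv.h_speed == pytest.approx(mv.g_speed, rel=1e-9)
        assert mv.h_bearing == pytest.approx(mv.g_bearing, abs=1e-9)
        assert mv.a_m == pytest.approx(mv.f_m, abs=1e-9)
        assert mv.f_m == pytest.approx(mv.g_speed * math.cos(math.radians(mv.delta)), rel=1e-9)

    def test_pure_tailwind(self):
        a, b = _step(180.0)
        mv = decompose_step(a, b, WindSample(0.0, -20.0), mu=180.0)
        assert mv.t_w == pytest.approx(20.0, abs=1e-9)
        assert mv.a_m == pytest.approx(30.0, rel=1e-4)

    def test_zero_time_difference_rejected(self):
        a, _ = _step(180.0)
        with pytest.raises(ValueError):
            decompose_step(a, a, WindSample(0.0, 0.0), mu=180.0)

    @pytest.mark.parametrize("bearing,mu,wind", [
        (170.0, 180.0, (15.0, -5.0)),
        (200.0, 185.0, (-25.0, 10.0)),
        (90.0, 100.0, (5.0, 30.0)),
    ])
    def test_triangle_closure_and_identities(self, bearing, mu, wind):
        a, b = _step(bearing)
        mv = decompose_step(a, b, WindSample(*wind), mu=mu)
        ge = mv.g_speed * math.sin(math.radians(mv.g_bearing))
        gn = mv.g_speed * math.cos(math.radians(mv.g_bearing))
        he = mv.h_speed * math.sin(math.radians(mv.h_bearing))
        hn = mv.h_speed * math.cos(math.radians(mv.h_bearing))
        assert ge == pytest.approx(he + wind[0], abs=1e-9)
        assert gn == pytest.approx(hn + wind[1], abs=1e-9)
        assert mv.f_m - mv.t_w - mv.a_m == pytest.approx(0.0, abs=1e-9)
        assert abs(mv.p_m) <= mv.g_speed + 1e-12
        assert mv.f_m == pytest.approx(mv.g_speed * math.cos(math.radians(mv.delta)), abs=1e-9)


class TestDriftRegressions:
    def _mv(self, p_m, p_w, f_m=45.0, t_w=5.0):
        return MotionVectors(
            g_speed=45.0, g_bearing=180.0, w=WindSample(0, 0), h_speed=40.0,
            h_bearing=180.0, delta=0.0, p_w=p_w, t_w=t_w, p_m=p_m, f_m=f_m,
            a_m=f_m - t_w, mu=180.0,
        )

    def test_exact_linear_tailwind_relation(self):
        rng = np.random.default_rng(0)
        steps = [
            self._mv(0.1 * tw, tw + 1.0, f_m=tw + 38.0, t_w=tw)
            for tw in rng.uniform(-20, 20, 30)
        ]
        fit = drift_regressions(steps)["fm_tw"]
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(38.0, abs=1e-9)
        assert fit.f_stat > 1e12  # zero residual up to rounding
        assert fit.p_value == pytest.approx(0.0, abs=1e-300)

    def test_degenerate_regressor_rejected(self):
        steps = [self._mv(1.0, 5.0) for _ in range(10)]
        with pytest.raises(ValueError):
            drift_regressions(steps)

    def test_grouped_estimator_removes_between_segment_attenuation(self):
        # two segments whose mean drift was absorbed into their own mu:
        # within-segment slope is 1, naive pooling attenuates it
        rng = np.random.default_rng(1)
        steps, groups = [], []
        for g, offset in enumerate((-12.0, 12.0)):
            for _ in range(40):
                pw = offset + rng.normal(0, 4)
                steps.append(self._mv(p_m=(pw - offset), p_w=pw, t_w=0.3 * pw))
                groups.append(g)
        pooled = drift_regressions(steps)["pm_pw"]
        within = drift_regressions(steps, groups=groups)["pm_pw"]
        assert within.slope == pytest.approx(1.0, abs=1e-9)
        assert pooled.slope < 0.7
        assert within.df_err == len(steps) - 3


class TestOvercompensation:
    def test_pure_cases(self):
        def mv(pm, pw):
            return TestDriftRegressions()._mv(pm, pw)

        opposite = [mv(-1.0, 1.0), mv(2.0, -3.0)]
        same = [mv(1.0, 1.0), mv(-2.0, -3.0)]
        assert overcompensation_fraction(opposite) == 1.0
        assert overcompensation_fraction(same) == 0.0

    def test_mixed_count_and_zero_exclusion(self):
        mv = TestDriftRegressions()._mv
        steps = [mv(-1, 1)] * 6 + [mv(1, 1)] * 4 + [mv(0.0, 5.0), mv(3.0, 0.0)]
        assert overcompensation_fraction(steps) == pytest.approx(0.6)


class TestCircMeanCI:
    def test_wraparound_mean(self):
        res = circ_mean_ci([350.0, 10.0], n_boot=200, seed=0)
        assert res.mean_deg == pytest.approx(0.0, abs=1e-9)

    def test_identical_angles_zero_width(self):
        res = circ_mean_ci([42.0] * 8, n_boot=200, seed=0)
        assert res.ci_low_deg == pytest.approx(res.ci_high_deg, abs=1e-9)
        assert res.contains(42.0)

    def test_seed_reproducibility(self):
        angles = list(np.random.default_rng(3).uniform(120, 240, 40))
        a = circ_mean_ci(angles, seed=7)
        b = circ_mean_ci(angles, seed=7)
        assert (a.ci_low_deg, a.ci_high_deg) == (b.ci_low_deg, b.ci_high_deg)

    def test_von_mises_coverage(self):
        # nominal 95% interval should cover the true mean (180°) in at
        # least 93 of 100 seeded replicates of 500 draws at kappa=4
        rng = np.random.default_rng(11)
        covered = 0
        for rep in range(100):
            draws = np.degrees(vonmises.rvs(4, loc=math.pi, size=500, random_state=rng)) % 360
            res = circ_mean_ci(draws, n_boot=1000, seed=rep)
            covered += res.contains(180.0)
        assert covered >= 93


class TestWatson:
    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 360, 15)
        b = rng.uniform(0, 360, 12)
        u1, _ = watson_two_sample(a, b, p_method="permutation", seed=1, n_perm=10)
        u2, _ = watson_two_sample((a + 117) % 360, (b + 117) % 360, p_method="permutation", seed=1, n_perm=10)
        assert u1 == pytest.approx(u2, abs=1e-12)

    def test_asymptotic_matches_published_critical_values(self):
        # the limiting tail reproduces the tabulated two-sample critical
        # values at the 10/5/1% levels
        for u2, alpha in ((0.152, 0.10), (0.187, 0.05), (0.268, 0.01)):
            p = 2.0 * math.exp(-2.0 * math.pi**2 * u2)
            assert p == pytest.approx(alpha, abs=0.002)

    def test_permutation_agrees_with_asymptotic_under_null(self):
        rng = np.random.default_rng(9)
        diffs = []
        for seed in range(5):
            a = rng.uniform(0, 360, 30)
            b = rng.uniform(0, 360, 30)
            _, p_asym = watson_two_sample(a, b, p_method="asymptotic")
            _, p_perm = watson_two_sample(a, b, p_method="permutation", seed=seed, n_perm=999)
            diffs.append(abs(min(p_asym, 1.0) - p_perm))
        assert np.median(diffs) < 0.02

    def test_power_against_shifted_von_mises(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(20):
            a = np.degrees(vonmises.rvs(8, loc=0.0, size=50, random_state=rng)) % 360
            b = np.degrees(vonmises.rvs(8, loc=math.pi / 2, size=50, random_state=rng)) % 360
            _, p = watson_two_sample(a, b)
            rejections += p < 0.05
        assert rejections >= 19

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            watson_two_sample([10.0] * 10, [10.0] * 10)

    def test_small_sample_needs_permutation(self):
        with pytest.raises(ValueError):
            watson_two_sample([1, 2, 3, 4], [5, 6, 7, 8], p_method="asymptotic")


class TestWindField:
    def _field(self):
        times = np.array(["2009-09-14T12:00", "2009-09-14T18:00"], dtype="datetime64[s]")
        lats = np.array([30.0, 35.0, 40.0])
        lons = np.array([-75.0, -70.0])
        u = np.arange(12, dtype=float).reshape(2, 3, 2)
        v = -np.arange(12, dtype=float).reshape(2, 3, 2)
        return WindField(times, lats, lons, u, v)

    def test_node_sampling_exact(self):
        wf = self._field()
        s = wf.sample(datetime(2009, 9, 14, 12), 35.0, -70.0)
        assert (s.u10, s.v10) == (3.0, -3.0)

    def test_csv_roundtrip(self, tmp_path):
        wf = self._field()
        path = tmp_path / "wind.csv"
        wf.to_csv(path)
        back = WindField.from_csv(path)
        assert np.allclose(back.u10, wf.u10)
        assert np.allclose(back.v10, wf.v10)
        assert np.array_equal(back.times, wf.times)

    def test_out_of_bounds_rejected(self):
        wf = self._field()
        with pytest.raises(ValueError):
            wf.sample(datetime(2009, 9, 14, 12), 50.0, -70.0)

    def test_wind_sample_polar_consistency(self):
        s = WindSample(10.0, 10.0)
        assert s.speed == pytest.approx(math.hypot(10, 10))
        assert s.direction_toward == pytest.approx(45.0)


def test_behaviour_recovery_partial_alpha_smoke():
    # quick end-to-end sanity at alpha=0.5 with a reduced world count
    steps, groups = behaviour_steps(0.5, "partial", n_tracks=4, seed0=40)
    fit = drift_regressions(steps, groups=groups)["pm_pw"]
    assert fit.slope == pytest.approx(0.5, abs=0.08)
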