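"""Grids, polynomial trend fitting and cross-space trajectory contrast."""

import math
from datetime import timedelta

import numpy as np
import pytest

from natalnav.geodesy import GeoPoint, mercator_project
from natalnav.magframe import NatalFrame
from natalnav.spacecompare import (
    CoordSpaceTrace,
    build_grid,
    compare_orders,
    fit_polynomial_hz,
    natal_straightness_table,
    pairwise_coefficient_tests,
    trace_tracks,
)
from natalnav.trackseg import GeoFix

from conftest import T0, straight_fixes


class TestBuildGrid:
    @pytest.mark.parametrize(
        "lat_b, lon_b, spacing, expected",
        [
            ((20, 42), (-78, -67), 0.5, 1035),  # the survey domain
            ((0, 1), (0, 1), 1.0, 4),
            ((0, 1), (0, 2), 0.5, 15),
        ],
    )
    def test_node_counts(self, lat_b, lon_b, spacing, expected):
        assert len(build_grid(lat_b, lon_b, spacing)) == expected

    def test_row_major_and_inclusive(self):
        g = build_grid((0, 1), (10, 11), 1.0)
        assert [(p.lat, p.lon) for p in g] == [(0, 10), (0, 11), (1, 10), (1, 11)]

    def test_nondividing_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 1), (0, 1), 0.3)


class TestPolynomialFit:
    def test_exact_cubic_recovered(self):
        x = np.linspace(-3, 3, 40)
        y = 1.5 - 2.0 * x + 0.5 * x**2 + 0.25 * x**3
        fit = fit_polynomial_hz(np.column_stack([x, y]), 3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients == pytest.approx([1.5, -2.0, 0.5, 0.25], rel=1e-8)

    def test_dipole_hz_curve_is_quartic_smooth(self, dipole):
        grid = build_grid((20, 42), (-78, -67), 0.5)
        els = [dipole.elements(p) for p in grid]
        pts = np.array([(e.H, e.Z) for e in els])
        fit = fit_polynomial_hz(pts, 4)
        assert fit.r2 > 0.99

    def test_saturated_order_rejected(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            fit_polynomial_hz(np.column_stack([x, x]), 4)


class TestCompareOrders:
    def test_quartic_data_selects_four(self):
        rng = np.random.default_rng(2)
        x = np.linspace(-2, 2, 120)
        y = 0.5 + x - 0.3 * x**2 + 0.1 * x**3 + 0.4 * x**4 + rng.normal(0, 0.2, 120)
        rec, table = compare_orders(np.column_stack([x, y]), [1, 2, 3, 4, 5])
        assert rec == 4
        assert table.loc[table["order_big"] == 5, "p"].iloc[0] > 0.05

    def test_linear_data_selects_one(self):
        rng = np.random.default_rng(3)
        x = np.linspace(-2, 2, 80)
        y = 2.0 * x + rng.normal(0, 0.1, 80)
        rec, _ = compare_orders(np.column_stack([x, y]), [1, 2, 3])
        assert rec == 1

    def test_noise_free_reported_saturated(self):
        x = np.linspace(-2, 2, 30)
        y = 1.0 + 2.0 * x
        _, table = compare_orders(np.column_stack([x, y]), [1, 2])
        assert bool(table["saturated"].iloc[0])

    def test_unordered_orders_rejected(self):
        with pytest.raises(ValueError):
            compare_orders(np.zeros((10, 2)), [3, 2])


class TestPairwiseTests:
    def _noisy_linear_trace(self, slope, seed, n=30, sid="s"):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 10, n)
        y = slope * x + rng.normal(0, 0.5, n)
        return CoordSpaceTrace("mercator", np.column_stack([x, y]), sid)

    def test_self_pair_not_significant(self):
        tr = self._noisy_linear_trace(1.0, 0, sid="a")
        tr2 = CoordSpaceTrace("mercator", tr.points.copy(), "b")
        m = pairwise_coefficient_tests([tr, tr2], model="linear")
        assert np.allclose(m.t[0, 1], 0.0)
        assert np.allclose(m.p[0, 1], 1.0)
        assert not m.significant[0, 1]

    def test_symmetry_and_unit_diagonal(self):
        traces = [self._noisy_linear_trace(s, i, sid=f"s{i}") for i, s in enumerate((1.0, 2.0, 0.5))]
        m = pairwise_coefficient_tests(traces, model="linear")
        assert np.allclose(m.p, np.transpose(m.p, (1, 0, 2)))
        assert np.allclose(m.t, -np.transpose(m.t, (1, 0, 2)))
        for i in range(3):
            assert np.all(m.p[i, i] == 1.0)
        assert not m.significant.diagonal().any()

    def test_t_statistic_matches_per_trace_fits(self):
        tr1 = self._noisy_linear_trace(1.0, 1, sid="a")
        tr2 = self._noisy_linear_trace(2.0, 2, sid="b")
        from natalnav.spacecompare import _polyfit

        f1 = _polyfit(tr1.points[:, 0], tr1.points[:, 1], 1)
        f2 = _polyfit(tr2.points[:, 0], tr2.points[:, 1], 1)
        expected = (f1.coefficients[1] - f2.coefficients[1]) / math.hypot(f1.se[1], f2.se[1])
        m = pairwise_coefficient_tests([tr1, tr2], model="linear")
        assert m.t[0, 1, 1] == pytest.approx(expected, rel=1e-12)
        assert m.df[0, 1] == 30 + 30 - 4
        assert m.significant[0, 1]

    def test_short_trace_excluded_with_warning(self):
        good = self._noisy_linear_trace(1.0, 3, sid="good")
        short = CoordSpaceTrace("mercator", np.array([[0.0, 0.0], [1.0, 1.0]]), "short")
        with pytest.warns(UserWarning, match="short"):
            m = pairwise_coefficient_tests([good, short], model="poly4")
        assert m.excluded == ["short"]
        assert m.segment_ids == ["good"]

    def test_bonferroni_tightens_alpha(self):
        traces = [self._noisy_linear_trace(s, i, sid=f"s{i}") for i, s in enumerate((1.0, 1.15))]
        plain = pairwise_coefficient_tests(traces, model="linear")
        bonf = pairwise_coefficient_tests(traces, model="linear", bonferroni=True)
        assert bonf.alpha == pytest.approx(plain.alpha / 2)


def _radial_track(bearing, n=12, step_km=45.0, start=(38.0, -72.5)):
    lat, lon = start
    fixes = []
    t = T0
    for _ in range(n):
        fixes.append(GeoFix(t, GeoPoint(lat, lon)))
        lat += step_km * math.cos(math.radians(bearing)) / 111.195
        lon += step_km * math.sin(math.radians(bearing)) / (111.195 * math.cos(math.radians(lat)))
        t += timedelta(hours=1)
    return fixes


class TestTraceTracks:
    def test_mercator_trace_matches_projection(self):
        fixes = straight_fixes(180.0, 5)
        (trace,) = trace_tracks({"seg": fixes}, "mercator")
        for f, row in zip(fixes, trace.points):
            q = mercator_project(f.position)
            assert row == pytest.approx((q.easting, q.northing), rel=1e-12)

    def test_nest_resident_track_sits_at_origin(self, dipole, nest_frame):
        fixes = [GeoFix(T0 + timedelta(hours=h), nest_frame.nest) for h in range(4)]
        (trace,) = trace_tracks(
            {"seg": fixes}, "yTzT", field_model=dipole, natal_frames={"seg": nest_frame}
        )
        assert np.allclose(trace.points, 0.0, atol=1e-8)

    def test_missing_frame_rejected(self, dipole):
        fixes = straight_fixes(180.0, 3)
        with pytest.raises(ValueError, match="natal frame"):
            trace_tracks({"seg": fixes}, "yTzT", field_model=dipole)

    def test_straightness_table_layout(self, dipole, nest_frame):
        segs = {f"s{i}": _radial_track(b) for i, b in enumerate((150.0, 210.0))}
        frames = {k: nest_frame for k in segs}
        traces = trace_tracks(segs, "yTzT", field_model=dipole, natal_frames=frames)
        tab = natal_straightness_table(traces)
        assert list(tab.columns) == ["segment_id", "straightness", "zT_se_nT", "yT_se_nT"]
        assert ((tab["straightness"] > 0) & (tab["straightness"] <= 1)).all()


class TestCoordinateSpaceDegeneracy:
    def test_fi_autocorrelated_but_natal_plane_is_not(self, dipole, nest_frame):
        # over the survey domain F and I are near-degenerate (quasi-1-D)
        # while y_T and z_T decorrelate for a nest off the magnetic
        # meridian of the grid
        grid = build_grid((20, 42), (-78, -67), 0.5)
        els = [dipole.elements(p) for p in grid]
        F = np.array([e.F for e in els])
        I = np.array([e.I for e in els])
        assert abs(np.corrcoef(F, I)[0, 1]) > 0.95
        from natalnav.magframe import natal_transform

        yz = np.array(
            [
                (lambda nc: (nc.y_T, nc.z_T))(natal_transform(dipole.xyz(p), nest_frame))
                for p in grid
            ]
        )
        assert abs(np.corrcoef(yz[:, 0], yz[:, 1])[0, 1]) < 0.5

    def test_radiating_segments_distinct_in_natal_plane_only(self, dipole, nest_frame):
        # segments leaving one origin at different bearings collapse
        # onto the common H-Z curve but separate in the y_T-z_T plane
        segs = {f"s{i}": _radial_track(b) for i, b in enumerate(np.linspace(120, 260, 25))}
        frames = {k: nest_frame for k in segs}
        hz = pairwise_coefficient_tests(
            trace_tracks(segs, "HZ_cartesian", field_model=dipole), model="poly4"
        )
        yz = pairwise_coefficient_tests(
            trace_tracks(segs, "yTzT", field_model=dipole, natal_frames=frames), model="linear"
        )
        assert hz.n_pairs == 300
        assert yz.proportion_significant > hz.proportion_significant
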