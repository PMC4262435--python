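"""Comparing track trajectories across coordinate spaces.

The same migration segment can be traced in several bicoordinate
spaces: Mercator (easting vs northing, km), geomagnetic polar (total
intensity F vs inclination I), its Cartesian equivalent (horizontal vs
vertical field intensity, H vs Z, nT) and the nest-origin transformed
magnetic plane (y_T vs z_T, nT).  Whether trajectories that are
distinct in one space remain distinct in another determines whether
that space could support positional orientation: a bicoordinate map is
only informative where its two coordinates are not degenerate.

Over the western Atlantic the F-I surface is strongly autocorrelated —
effectively one-dimensional — so all tracks collapse onto a single
smooth H-Z curve (fit here by low-order polynomial regression with
nested-model order selection), whereas the y_T-z_T plane retains
resolution.  The quantitative instrument is the pairwise comparison of
per-segment regression coefficients: for every pair of segments each
coefficient is compared by a two-sample t-test and the proportion of
significantly different pairs is reported per space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import EARTH_RADIUS_KM, GeoPoint, mercator_project
from .magframe import NatalFrame, natal_transform
from .trackseg import GeoFix, straightness_index

__all__ = [
    "CoordSpaceTrace",
    "PolyFit",
    "PairwiseTestMatrix",
    "build_grid",
    "fit_polynomial_hz",
    "compare_orders",
    "pairwise_coefficient_tests",
    "trace_tracks",
    "natal_straightness_table",
]

Space = Literal["mercator", "FI_polar", "HZ_cartesian", "yTzT"]

_SPACE_UNITS = {
    "mercator": ("easting_km", "northing_km"),
    "FI_polar": ("F_nT", "I_deg"),
    "HZ_cartesian": ("H_nT", "Z_nT"),
    "yTzT": ("yT_nT", "zT_nT"),
}


@dataclass(frozen=True)
class CoordSpaceTrace:
    """One segment's trajectory expressed in one coordinate space."""

    space: Space
    points: np.ndarray  # (n, 2)
    segment_id: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("trace points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)

    @property
    def axis_labels(self) -> tuple[str, str]:
        return _SPACE_UNITS[self.space]

    def straightness(self) -> float:
        """Euclidean-plane Batschelet straightness of the trace."""
        return straightness_index(self.points, metric="euclidean_plane")

    def to_dataframe(self) -> pd.DataFrame:
        a, b = self.axis_labels
        return pd.DataFrame({"segment_id": self.segment_id, a: self.points[:, 0], b: self.points[:, 1]})


def build_grid(
    lat_bounds: tuple[float, float],
    lon_bounds: tuple[float, float],
    spacing: float,
) -> list[GeoPoint]:
    """Regular lat-lon grid, boundary rows/columns included, row-major.

    ``spacing`` must divide both extents; the standard survey domain
    for the western Atlantic study region, 20-42°N x 78-67°W at 0.5°,
    yields 45 x 23 = 1035 nodes.
    """
    (lat0, lat1), (lon0, lon1) = sorted(lat_bounds), sorted(lon_bounds)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    for lo, hi, name in ((lat0, lat1, "lat"), (lon0, lon1, "lon")):
        n = (hi - lo) / spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"spacing {spacing} does not divide the {name} extent {hi - lo}")
    n_lat = round((lat1 - lat0) / spacing) + 1
    n_lon = round((lon1 - lon0) / spacing) + 1
    return [
        GeoPoint(lat0 + i * spacing, lon0 + j * spacing)
        for i in range(n_lat)
        for j in range(n_lon)
    ]


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial fit of y on powers of x."""

    order: int
    coefficients: np.ndarray  # ascending powers, len order+1
    se: np.ndarray
    r2: float
    rss: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)


def _polyfit(x: np.ndarray, y: np.ndarray, order: int) -> PolyFit:
    """Polynomial least squares, numerically fit on a centred/scaled
    regressor (field intensities are ~1e4 nT, so raw 4th powers are
    catastrophically ill-conditioned) with coefficients and covariance
    mapped back to the raw basis."""
    n = len(x)
    if n <= order + 1:
        raise ValueError(f"{n} points cannot support an order-{order} polynomial")
    c = float(np.mean(x))
    s = float(np.std(x))
    if s == 0.0:
        raise ValueError("rank-deficient design: x values do not support this order")
    xs = (x - c) / s
    X = np.vander(xs, order + 1, increasing=True)
    if np.linalg.matrix_rank(X) < order + 1:
        raise ValueError("rank-deficient design: x values do not support this order")
    b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    rss = float(resid @ resid)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    dof = n - (order + 1)
    sigma2 = rss / dof if dof > 0 else 0.0
    cov_b = sigma2 * np.linalg.pinv(X.T @ X)
    # basis change: ((x-c)/s)^j = sum_m comb(j,m) (-c)^(j-m) s^(-j) x^m
    T = np.zeros((order + 1, order + 1))
    for j in range(order + 1):
        for m in range(j + 1):
            T[m, j] = math.comb(j, m) * (-c) ** (j - m) / s**j
    beta = T @ b
    cov = T @ cov_b @ T.T
    return PolyFit(
        order=order,
        coefficients=beta,
        se=np.sqrt(np.maximum(np.diag(cov), 0.0)),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        rss=rss,
        n=n,
    )


def fit_polynomial_hz(points: Sequence, order: int, orientation: Literal["z_on_h", "h_on_z"] = "z_on_h") -> PolyFit:
    """Polynomial fit to an H-Z (horizontal vs vertical intensity) cloud.

    By default the vertical component Z is regressed on powers of the
    horizontal component H; swap with ``orientation="h_on_z"``.
    """
    arr = np.asarray(points, dtype=float)
    x, y = (arr[:, 0], arr[:, 1]) if orientation == "z_on_h" else (arr[:, 1], arr[:, 0])
    return _polyfit(x, y, order)


def compare_orders(
    points: Sequence,
    orders: Sequence[int],
    alpha: float = 0.05,
    orientation: Literal["z_on_h", "h_on_z"] = "z_on_h",
) -> tuple[int, pd.DataFrame]:
    """Sequential nested-model F-tests between consecutive orders.

    Returns the recommended order — the highest order whose gain over
    the previous one is significant at ``alpha`` — and the score table.
    A zero-residual larger model is reported as saturated (F undefined).
    """
    orders = list(orders)
    if any(b <= a for a, b in zip(orders[:-1], orders[1:])):
        raise ValueError("orders must be strictly ascending")
    arr = np.asarray(points, dtype=float)
    x, y = (arr[:, 0], arr[:, 1]) if orientation == "z_on_h" else (arr[:, 1], arr[:, 0])
    fits = {k: _polyfit(x, y, k) for k in orders}
    tss = float(np.sum((y - np.mean(y)) ** 2))
    rows = []
    recommended = orders[0]
    for small, big in zip(orders[:-1], orders[1:]):
        f_small, f_big = fits[small], fits[big]
        df_small = f_small.n - (small + 1)
        df_big = f_big.n - (big + 1)
        if f_big.rss <= 1e-12 * tss:
            rows.append(
                {"order_small": small, "order_big": big, "F": math.nan, "p": math.nan,
                 "df1": df_small - df_big, "df2": df_big, "saturated": True}
            )
            continue
        F = ((f_small.rss - f_big.rss) / (df_small - df_big)) / (f_big.rss / df_big)
        p = float(stats.f.sf(F, df_small - df_big, df_big))
        rows.append(
            {"order_small": small, "order_big": big, "F": F, "p": p,
             "df1": df_small - df_big, "df2": df_big, "saturated": False}
        )
        if p < alpha:
            recommended = big
    return recommended, pd.DataFrame(rows)


@dataclass
class PairwiseTestMatrix:
    """All-pairs regression-coefficient t-tests between segment traces.

    ``t`` and ``p`` have shape (n_traces, n_traces, n_coefficients);
    ``df`` is (n, n).  A pair is 'significantly different' when any of
    its coefficients differs at ``alpha`` (two-tailed); the diagonal is
    never significant.  Traces too short for the model are excluded and
    listed in ``excluded``.
    """

    segment_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    coefficient_order: list[str]
    alpha: float
    excluded: list[str] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        sig = np.any(self.p < self.alpha, axis=2)
        np.fill_diagonal(sig, False)
        return sig

    @property
    def n_pairs(self) -> int:
        n = len(self.segment_ids)
        return n * (n - 1) // 2

    @property
    def proportion_significant(self) -> float:
        n = len(self.segment_ids)
        iu = np.triu_indices(n, k=1)
        return float(np.mean(self.significant[iu])) if self.n_pairs else math.nan

    def p_dataframe(self, coefficient: int = -1) -> pd.DataFrame:
        """p-value matrix for one coefficient (default: highest order)."""
        return pd.DataFrame(
            self.p[:, :, coefficient], index=self.segment_ids, columns=self.segment_ids
        )


def pairwise_coefficient_tests(
    traces: Sequence[CoordSpaceTrace],
    model: Literal["linear", "poly4"] = "linear",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> PairwiseTestMatrix:
    """Two-sample t-tests on per-segment regression coefficients.

    Each trace's second coordinate is regressed on powers of the first
    (order 1 or 4).  For a pair of traces and coefficient j,
    t = (b1j - b2j)/sqrt(SE1j² + SE2j²) with df = n1 + n2 - 2(k+1).
    No multiplicity correction is applied by default (each pair is
    tested on its own); ``bonferroni=True`` divides alpha by the number
    of coefficients tested per pair.
    """
    order = 1 if model == "linear" else 4
    kept: list[CoordSpaceTrace] = []
    fits: list[PolyFit] = []
    excluded: list[str] = []
    for tr in traces:
        try:
            fits.append(_polyfit(tr.points[:, 0], tr.points[:, 1], order))
            kept.append(tr)
        except ValueError:
            excluded.append(tr.segment_id)
            warnings.warn(
                f"segment {tr.segment_id!r} too short for order-{order} model; excluded",
                stacklevel=2,
            )
    n = len(kept)
    k1 = order + 1
    t = np.zeros((n, n, k1))
    p = np.ones((n, n, k1))
    df = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            fi, fj = fits[i], fits[j]
            dof = fi.n + fj.n - 2 * k1
            denom = np.sqrt(fi.se**2 + fj.se**2)
            with np.errstate(divide="ignore", invalid="ignore"):
                tij = np.where(denom > 0, (fi.coefficients - fj.coefficients) / denom, 0.0)
            pij = 2.0 * stats.t.sf(np.abs(tij), dof)
            t[i, j], t[j, i] = tij, -tij
            p[i, j], p[j, i] = pij, pij
            df[i, j] = df[j, i] = dof
    eff_alpha = alpha / k1 if bonferroni else alpha
    return PairwiseTestMatrix(
        segment_ids=[tr.segment_id for tr in kept],
        t=t,
        p=p,
        df=df,
        coefficient_order=[f"x^{m}" for m in range(k1)],
        alpha=eff_alpha,
        excluded=excluded,
    )


def trace_tracks(
    segments: Mapping[str, Sequence[GeoFix]],
    space: Space,
    field_model=None,
    natal_frames: Mapping[str, NatalFrame] | None = None,
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> list[CoordSpaceTrace]:
    """Express every segment's fixes in the requested coordinate space.

    ``field_model`` (anything with an ``elements(GeoPoint)`` method) is
    required for the magnetic spaces; ``natal_frames`` maps segment id
    to its bird's :class:`NatalFrame` and is required for ``yTzT``.
    """
    if space not in _SPACE_UNITS:
        raise ValueError(f"unknown space {space!r}")
    traces = []
    for seg_id, fixes in segments.items():
        pts = np.empty((len(fixes), 2))
        for i, f in enumerate(fixes):
            pos = f.position
            if space == "mercator":
                q = mercator_project(pos, earth_radius_km)
                pts[i] = (q.easting, q.northing)
            else:
                if field_model is None:
                    raise ValueError("magnetic spaces require a field model")
                el = field_model.elements(pos)
                if space == "FI_polar":
                    pts[i] = (el.F, el.I)
                elif space == "HZ_cartesian":
                    pts[i] = (el.H, el.Z)
                else:  # yTzT
                    if natal_frames is None or seg_id not in natal_frames:
                        raise ValueError(f"no natal frame for segment {seg_id!r}")
                    nc = natal_transform((el.X, el.Y, el.Z), natal_frames[seg_id])
                    pts[i] = (nc.y_T, nc.z_T)
        traces.append(CoordSpaceTrace(space=space, points=pts, segment_id=seg_id))
    return traces


def natal_straightness_table(traces: Sequence[CoordSpaceTrace]) -> pd.DataFrame:
    """Per-segment straightness and per-axis SEs in the y_T-z_T plane.

    The two SE columns are the residual standard errors of the two
    orientations of the linear trace fit (z_T on y_T and y_T on z_T) —
    a summary of how tightly the trace hugs its own straight line on
    each axis, in nT.
    """
    rows = []
    for tr in traces:
        if tr.space != "yTzT":
            raise ValueError("natal straightness table expects yTzT traces")
        y, z = tr.points[:, 0], tr.points[:, 1]
        n = len(y)
        se_z = se_y = math.nan
        if n > 2:
            if np.ptp(y) > 0:
                fit_zy = _polyfit(y, z, 1)
                se_z = math.sqrt(fit_zy.rss / (n - 2))
            if np.ptp(z) > 0:
                fit_yz = _polyfit(z, y, 1)
                se_y = math.sqrt(fit_yz.rss / (n - 2))
        rows.append(
            {
                "segment_id": tr.segment_id,
                "straightness": tr.straightness(),
                "zT_se_nT": se_z,
                "yT_se_nT": se_y,
            }
        )
    return pd.DataFrame(rows)
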