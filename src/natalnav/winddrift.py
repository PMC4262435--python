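"""Wind-triangle decomposition of hourly track steps and drift statistics.

For every step between consecutive GPS fixes the observed groundtrack
vector g is the sum of the wind vector w and the bird's heading
(airspeed) vector h — the classic wind triangle.  Relative to the
segment's mean track direction μ the step decomposes into:

* drift angle δ = groundtrack bearing − μ,
* forward movement f_m = |g| cos δ and perpendicular movement
  p_m = |g| sin δ (positive to the right of μ),
* tailwind t_w and perpendicular wind p_w — the wind components
  parallel and perpendicular to μ,
* active forward movement a_m = f_m − t_w, the bird's own contribution
  to progress along the course.

A bird drifting freely shows p_m tracking p_w one-to-one; a fully
compensating bird shows no relation between them.  The module provides
the per-step decomposition, the three drift regressions (p_m~p_w,
f_m~t_w, a_m~t_w) with ANOVA F-tests, the overcompensation fraction,
and the circular statistics used on heading/track/wind directions:
bootstrap von Mises mean confidence intervals and the Watson two-sample
U² test of homogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geodesy import GeoPoint, rhumb_bearing, rhumb_distance
from .trackseg import GeoFix

__all__ = [
    "WindSample",
    "WindField",
    "MotionVectors",
    "decompose_step",
    "decompose_segment",
    "DriftRegression",
    "drift_regressions",
    "overcompensation_fraction",
    "circ_mean_ci",
    "watson_two_sample",
]


def _bearing_of(east: float, north: float) -> float:
    b = math.degrees(math.atan2(east, north)) % 360.0
    return 0.0 if b >= 360.0 else b  # -0.0 % 360 rounds to 360.0


def _wrap180(angle: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


@dataclass(frozen=True)
class WindSample:
    """10 m wind at one place and time, km/h, meteorological components.

    ``u10`` is the eastward and ``v10`` the northward component;
    ``direction_toward`` is the bearing the wind blows toward.
    """

    u10: float
    v10: float

    @property
    def speed(self) -> float:
        return math.hypot(self.u10, self.v10)

    @property
    def direction_toward(self) -> float:
        return _bearing_of(self.u10, self.v10)


@dataclass(frozen=True)
class MotionVectors:
    """The full vector set for one hourly step (speeds km/h, angles deg)."""

    g_speed: float
    g_bearing: float
    w: WindSample
    h_speed: float
    h_bearing: float
    delta: float
    p_w: float
    t_w: float
    p_m: float
    f_m: float
    a_m: float
    mu: float


class WindField:
    """A gridded U10/V10 wind field on regular (time, lat, lon) axes.

    Sampling uses trilinear interpolation.  Time is carried as
    ``numpy.datetime64``; sampling accepts datetimes or timestamps.
    The on-disk format is a long CSV with columns
    (time, lat, lon, u10, v10); ``to_netcdf`` additionally writes a
    CF-style NetCDF through xarray when that stack is available.
    """

    def __init__(self, times, lats, lons, u10: np.ndarray, v10: np.ndarray):
        self.times = np.asarray(times, dtype="datetime64[s]")
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        self.u10 = np.asarray(u10, dtype=float)
        self.v10 = np.asarray(v10, dtype=float)
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u10.shape != shape or self.v10.shape != shape:
            raise ValueError(f"component arrays must have shape {shape}")
        for ax, name in ((self.lats, "lat"), (self.lons, "lon")):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        self._t0 = self.times[0]
        self._th = (self.times - self._t0) / np.timedelta64(1, "h")
        from scipy.interpolate import RegularGridInterpolator

        axes = (self._th, self.lats, self.lons)
        self._iu = RegularGridInterpolator(axes, self.u10, bounds_error=True)
        self._iv = RegularGridInterpolator(axes, self.v10, bounds_error=True)

    def sample(self, time, lat: float, lon: float) -> WindSample:
        th = (np.datetime64(pd.Timestamp(time), "s") - self._t0) / np.timedelta64(1, "h")
        pt = np.array([[float(th), float(lat), float(lon)]])
        return WindSample(float(self._iu(pt)[0]), float(self._iv(pt)[0]))

    def to_dataframe(self) -> pd.DataFrame:
        tt, la, lo = np.meshgrid(self.times, self.lats, self.lons, indexing="ij")
        return pd.DataFrame(
            {
                "time": tt.ravel(),
                "lat": la.ravel(),
                "lon": lo.ravel(),
                "u10": self.u10.ravel(),
                "v10": self.v10.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindField":
        df = pd.read_csv(path, parse_dates=["time"])
        times = np.sort(df["time"].unique())
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        shape = (len(times), len(lats), len(lons))
        df = df.sort_values(["time", "lat", "lon"])
        if len(df) != shape[0] * shape[1] * shape[2]:
            raise ValueError("wind CSV does not describe a complete regular grid")
        return cls(
            times,
            lats,
            lons,
            df["u10"].to_numpy().reshape(shape),
            df["v10"].to_numpy().reshape(shape),
        )

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {
                "u10": (("time", "lat", "lon"), self.u10),
                "v10": (("time", "lat", "lon"), self.v10),
            },
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
        )
        ds.u10.attrs["units"] = "km h-1"
        ds.v10.attrs["units"] = "km h-1"
        ds.to_netcdf(path, engine="scipy")


def decompose_step(
    fix_a: GeoFix, fix_b: GeoFix, wind: WindSample, mu: float
) -> MotionVectors:
    """Decompose one step into the wind-triangle vector set.

    ``mu`` is the segment's mean track direction in degrees.  The
    heading vector is recovered as h = g − w; perpendicular components
    are signed positive to the right of μ.
    """
    dt_h = (fix_b.timestamp - fix_a.timestamp).total_seconds() / 3600.0
    if dt_h <= 0:
        raise ValueError("step requires strictly increasing timestamps")
    d = rhumb_distance(fix_a.position, fix_b.position)
    g_speed = d / dt_h
    g_bearing = rhumb_bearing(fix_a.position, fix_b.position) if d > 0 else mu
    ge, gn = g_speed * math.sin(math.radians(g_bearing)), g_speed * math.cos(
        math.radians(g_bearing)
    )
    he, hn = ge - wind.u10, gn - wind.v10
    mu = mu % 360.0
    along = (math.sin(math.radians(mu)), math.cos(math.radians(mu)))
    right = (math.cos(math.radians(mu)), -math.sin(math.radians(mu)))
    delta = _wrap180(g_bearing - mu)
    return MotionVectors(
        g_speed=g_speed,
        g_bearing=g_bearing,
        w=wind,
        h_speed=math.hypot(he, hn),
        h_bearing=_bearing_of(he, hn),
        delta=delta,
        p_w=wind.u10 * right[0] + wind.v10 * right[1],
        t_w=wind.u10 * along[0] + wind.v10 * along[1],
        p_m=g_speed * math.sin(math.radians(delta)),
        f_m=g_speed * math.cos(math.radians(delta)),
        a_m=g_speed * math.cos(math.radians(delta))
        - (wind.u10 * along[0] + wind.v10 * along[1]),
        mu=mu,
    )


def decompose_segment(
    fixes: Sequence[GeoFix],
    windfield: WindField,
    mu: float,
    max_gap_h: float = 2.0,
    wind_at: Literal["midpoint", "start"] = "midpoint",
) -> list[MotionVectors]:
    """Decompose every consecutive-fix step of a segment.

    The wind is interpolated trilinearly in (time, lat, lon).  Because
    an hourly step integrates the wind over the whole hour, sampling at
    the step's temporal and spatial midpoint (the default) is the least
    biased single-point summary of the wind that actually displaced the
    bird; ``wind_at="start"`` samples at the starting fix instead.
    Steps longer than ``max_gap_h`` — the overnight duty-cycle gap —
    are skipped.
    """
    out = []
    for a, b in zip(fixes[:-1], fixes[1:]):
        dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
        if dt_h <= 0:
            raise ValueError("timestamps must be strictly increasing")
        if dt_h > max_gap_h:
            continue
        if wind_at == "midpoint":
            when = a.timestamp + (b.timestamp - a.timestamp) / 2
            lat = 0.5 * (a.position.lat + b.position.lat)
            lon = 0.5 * (a.position.lon + b.position.lon)
        else:
            when, lat, lon = a.timestamp, a.position.lat, a.position.lon
        wind = windfield.sample(when, lat, lon)
        out.append(decompose_step(a, b, wind, mu))
    return out


@dataclass(frozen=True)
class DriftRegression:
    response: str
    regressor: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    f_stat: float
    p_value: float
    df_reg: int
    df_err: int
    n: int


def _ols(
    y: np.ndarray,
    x: np.ndarray,
    response: str,
    regressor: str,
    groups: np.ndarray | None = None,
) -> DriftRegression:
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate regressor {regressor}: no variation")
    if groups is None:
        model = sm.OLS(y, sm.add_constant(x)).fit()
        slope = float(model.params[1])
        intercept = float(model.params[0])
        slope_se = float(model.bse[1])
        intercept_se = float(model.bse[0])
        df_err = int(model.df_resid)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = float(model.fvalue)  # 0/0 on an exact fit; mapped below
            p = float(model.f_pvalue)
    else:
        # within-group (fixed-effect) estimator: demean per group and
        # correct the residual df for the absorbed intercepts
        labels, inv = np.unique(groups, return_inverse=True)
        xd = x - np.bincount(inv, weights=x)[inv] / np.bincount(inv)[inv]
        yd = y - np.bincount(inv, weights=y)[inv] / np.bincount(inv)[inv]
        if np.ptp(xd) == 0:
            raise ValueError(f"degenerate regressor {regressor}: no within-group variation")
        slope = float(xd @ yd / (xd @ xd))
        resid = yd - slope * xd
        df_err = len(y) - len(labels) - 1
        if df_err < 1:
            raise ValueError("too few observations for the grouped fit")
        sigma2 = float(resid @ resid) / df_err
        slope_se = math.sqrt(sigma2 / float(xd @ xd))
        intercept = float(np.mean(y) - slope * np.mean(x))  # grand intercept
        intercept_se = math.nan
        ess = slope**2 * float(xd @ xd)
        f = ess / sigma2 if sigma2 > 0 else math.inf
        p = float(stats.f.sf(f, 1, df_err)) if math.isfinite(f) else 0.0
    if not math.isfinite(f):  # exact linear data: zero residual
        f, p = math.inf, 0.0
    return DriftRegression(
        response=response,
        regressor=regressor,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        f_stat=f,
        p_value=p,
        df_reg=1,
        df_err=df_err,
        n=len(y),
    )


def drift_regressions(
    steps: Iterable[MotionVectors], groups: Sequence | None = None
) -> dict[str, DriftRegression]:
    """The three drift-compensation OLS fits with ANOVA F-tests.

    Keys: ``"pm_pw"`` (perpendicular movement on perpendicular wind —
    slope 1 under full drift, 0 under full compensation), ``"fm_tw"``
    (forward movement on tailwind; the intercept is the zero-wind
    forward movement velocity) and ``"am_tw"`` (active forward movement
    on tailwind — negative under airspeed adjustment to headwinds).

    When steps are pooled across segments, each segment's mean track
    direction absorbs that segment's mean drift, so only within-segment
    variation is informative about the compensation behaviour; passing
    per-step segment labels as ``groups`` fits segment fixed effects
    (within-segment estimator) with the residual df reduced by the
    number of absorbed intercepts.
    """
    steps = list(steps)
    if len(steps) < 3:
        raise ValueError("drift regressions need at least 3 steps")
    if groups is not None:
        groups = np.asarray(list(groups))
        if len(groups) != len(steps):
            raise ValueError("groups must label every step")
    p_m = np.array([s.p_m for s in steps])
    p_w = np.array([s.p_w for s in steps])
    f_m = np.array([s.f_m for s in steps])
    t_w = np.array([s.t_w for s in steps])
    a_m = np.array([s.a_m for s in steps])
    return {
        "pm_pw": _ols(p_m, p_w, "p_m", "p_w", groups),
        "fm_tw": _ols(f_m, t_w, "f_m", "t_w", groups),
        "am_tw": _ols(a_m, t_w, "a_m", "t_w", groups),
    }


def overcompensation_fraction(steps: Iterable[MotionVectors]) -> float:
    """Fraction of steps whose p_m and p_w have opposite signs.

    Overcompensation means the bird moved into the perpendicular wind.
    Steps where either component is exactly zero are excluded from both
    numerator and denominator.
    """
    signs = [
        (s.p_m, s.p_w) for s in steps if s.p_m != 0.0 and s.p_w != 0.0
    ]
    if not signs:
        raise ValueError("no steps with nonzero perpendicular components")
    opposite = sum(1 for pm, pw in signs if pm * pw < 0)
    return opposite / len(signs)


# ---------------------------------------------------------------------------
# circular statistics


def _circ_mean_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    rad = np.radians(angles_deg)
    C, S = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    rbar = float(np.hypot(C, S))
    return _bearing_of(float(S), float(C)), rbar


def _kappa_from_rbar(rbar: float, n: int) -> float:
    """Best & Fisher approximation to the von Mises concentration."""
    if rbar >= 1.0 - 1e-12:
        return math.inf
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    if n < 15 and k < 2:  # small-sample bias correction
        k = max(k - 2 / (n * k), 0.0)
    return float(k)


@dataclass(frozen=True)
class CircMeanCI:
    mean_deg: float
    ci_low_deg: float
    ci_high_deg: float
    kappa: float
    rbar: float
    n_boot: int

    def contains(self, angle_deg: float) -> bool:
        """Whether the (wrap-aware) CI covers ``angle_deg``."""
        off_lo = _wrap180(self.ci_low_deg - self.mean_deg)
        off_hi = _wrap180(self.ci_high_deg - self.mean_deg)
        off = _wrap180(angle_deg - self.mean_deg)
        return off_lo <= off <= off_hi


def circ_mean_ci(
    angles_deg: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> CircMeanCI:
    """Circular mean with a bootstrap percentile confidence interval.

    Resamples the angles with replacement ``n_boot`` times, takes the
    circular mean of each resample, and forms the percentile interval
    of the (wrapped) deviations of the bootstrap means from the point
    estimate — the standard bootstrap analogue of fitting a von Mises
    mean.  Also reports the von Mises concentration estimated from the
    resultant length.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if len(angles) < 2:
        raise ValueError("need at least 2 angles")
    mean, rbar = _circ_mean_deg(angles)
    if rbar < 1e-12:
        raise ValueError("resultant length ~0: circular mean undefined")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(angles), size=(n_boot, len(angles)))
    rad = np.radians(angles[idx])
    boot_means = np.degrees(
        np.arctan2(np.mean(np.sin(rad), axis=1), np.mean(np.cos(rad), axis=1))
    )
    dev = np.array([_wrap180(b - mean) for b in boot_means])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(dev, [alpha, 1.0 - alpha])
    return CircMeanCI(
        mean_deg=mean,
        ci_low_deg=(mean + lo) % 360.0,
        ci_high_deg=(mean + hi) % 360.0,
        kappa=_kappa_from_rbar(rbar, len(angles)),
        rbar=rbar,
        n_boot=n_boot,
    )


def _watson_u2(a: np.ndarray, b: np.ndarray) -> float:
    """Watson two-sample U² from pooled empirical CDF differences.

    Ties are handled by evaluating the CDF difference once per distinct
    pooled value, weighted by its multiplicity (midrank-equivalent).
    """
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    values, counts = np.unique(pooled, return_counts=True)
    fa = np.searchsorted(np.sort(a), values, side="right") / n
    fb = np.searchsorted(np.sort(b), values, side="right") / m
    d = fa - fb
    N = n + m
    dbar = np.sum(counts * d) / N
    return float(n * m / N**2 * np.sum(counts * (d - dbar) ** 2))


def watson_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    p_method: Literal["asymptotic", "permutation"] = "asymptotic",
    seed: int | None = None,
    n_perm: int = 9999,
) -> tuple[float, float]:
    """Watson U² test of homogeneity for two circular samples (degrees).

    U² is rotation-invariant: adding a common rotation to both samples
    leaves it unchanged.  The asymptotic p-value uses the limiting tail
    P(U² > u) = 2·exp(−2π²u), which reproduces the standard critical
    values 0.152/0.187/0.268 at α = 0.10/0.05/0.01 and requires at
    least 8 observations per sample; the permutation p-value reassigns
    pooled observations to the two samples ``n_perm`` times.
    Returns ``(u2, p)``.
    """
    a = np.asarray(a, dtype=float) % 360.0
    b = np.asarray(b, dtype=float) % 360.0
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 angles")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        raise ValueError("degenerate input: all angles identical")
    u2 = _watson_u2(a, b)
    if p_method == "asymptotic":
        if len(a) < 8 or len(b) < 8:
            raise ValueError("asymptotic p requires >= 8 angles per sample")
        p = min(1.0, 2.0 * math.exp(-2.0 * math.pi**2 * u2))
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _watson_u2(perm[: len(a)], perm[len(a):]) >= u2 - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return u2, p
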