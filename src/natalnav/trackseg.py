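"""Track data model, piecewise-linear segmentation and straightness.

A migration track is an ordered sequence of hourly GPS fixes.  The
trans-oceanic part of a track is split into constant-course segments by
piecewise linear regression breakpoint analysis on Mercator-projected
coordinates: a continuous broken-line model is fitted by iterative
linearization (with an exhaustive grid-search fallback on small
instances), and the number of breakpoints can be chosen by BIC.  Each
segment is then summarised by distance travelled, duration, mean hourly
ground speed, circular-mean track direction and the Batschelet
straightness index — the ratio of the endpoint rhumb-line distance to
the distance actually travelled, 1 for a perfectly straight movement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geodesy import (
    EARTH_RADIUS_KM,
    GeoPoint,
    PlanePoint,
    mercator_project,
    path_length,
    rhumb_bearing,
    rhumb_distance,
)

__all__ = [
    "GeoFix",
    "TrackSegment",
    "SegmentSummary",
    "PiecewiseFit",
    "PiecewiseFitError",
    "fit_piecewise_linear",
    "select_n_breakpoints",
    "segment_track",
    "straightness_index",
    "summarize_segment",
    "read_track_csv",
    "write_summary_table",
]

# Per-step statistics never span sampling gaps longer than this (the
# tags sample hourly over a 12 h duty cycle; overnight gaps are ~12 h).
MAX_STEP_GAP_H = 2.0


@dataclass(frozen=True)
class GeoFix:
    """One timestamped GPS position (altitude in metres, optional)."""

    timestamp: datetime
    position: GeoPoint
    altitude: float | None = None


@dataclass(frozen=True)
class SegmentSummary:
    distance_km: float
    duration_h: float
    speed_kmh: float
    speed_sd: float
    direction_deg: float
    direction_sd: float
    straightness: float
    n_fixes: int


@dataclass(frozen=True)
class TrackSegment:
    """A contiguous run of fixes belonging to one constant-course piece."""

    fixes: tuple[GeoFix, ...]
    start_index: int
    stop_index: int  # exclusive
    summary: SegmentSummary
    breakpoint_coords: tuple[PlanePoint, ...] = ()


class PiecewiseFitError(RuntimeError):
    """Raised when the iterative broken-line fit fails; carries the last
    iterate in ``last_fit`` when one exists."""

    def __init__(self, message: str, last_fit: "PiecewiseFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class PiecewiseFit:
    """A continuous broken-line fit y = a_i + b_i * x on each piece."""

    breakpoints: np.ndarray           # sorted interior breakpoints (x units)
    breakpoint_se: np.ndarray
    slopes: np.ndarray                # one per piece, len = k+1
    intercepts: np.ndarray
    slope_se: np.ndarray
    rss: float
    n_obs: int
    converged: bool
    n_iter: int
    method: str = "muggeo"

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        piece = np.searchsorted(self.breakpoints, x, side="right")
        return self.intercepts[piece] + self.slopes[piece] * x

    def bic(self) -> float:
        # 2 line params + 2 per breakpoint (position + slope change) + σ
        k = 3 + 2 * self.n_breakpoints
        n = self.n_obs
        return n * math.log(max(self.rss, 1e-300) / n) + k * math.log(n)


def _xy_arrays(
    xy: Sequence, orientation: Literal["easting_on_northing", "northing_on_easting"]
) -> tuple[np.ndarray, np.ndarray]:
    pts = [(p.easting, p.northing) if isinstance(p, PlanePoint) else tuple(p) for p in xy]
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("xy must be a sequence of 2-D points")
    e, n = arr[:, 0], arr[:, 1]
    if orientation == "easting_on_northing":
        return n, e  # regressor x = northing, regressand y = easting
    return e, n


def _broken_line_ls(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """Least-squares continuous broken-line fit at fixed breakpoints.

    Returns (beta, rss, cov) for the basis [1, x, (x-psi_1)+, ...].
    """
    cols = [np.ones_like(x), x] + [np.clip(x - p, 0.0, None) for p in psi]
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = max(len(x) - X.shape[1], 1)
    sigma2 = rss / dof
    XtX = X.T @ X
    cov = sigma2 * np.linalg.pinv(XtX)
    return beta, rss, cov


def _fit_from_psi(x, y, psi, converged, n_iter, psi_se=None, method="muggeo") -> PiecewiseFit:
    psi = np.sort(np.asarray(psi, dtype=float))
    beta, rss, cov = _broken_line_ls(x, y, psi)
    k = len(psi)
    # piecewise slopes are cumulative sums of the slope-change coefs
    slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:2 + k]]))
    intercepts = np.empty(k + 1)
    intercepts[0] = beta[0]
    for j in range(k):
        # continuity at psi_j pins each successive intercept
        intercepts[j + 1] = intercepts[j] + (slopes[j] - slopes[j + 1]) * psi[j]
    slope_se = np.sqrt(np.maximum(np.diag(cov)[1:2 + k], 0.0))
    if psi_se is None:
        psi_se = np.full(k, np.nan)
    return PiecewiseFit(
        breakpoints=psi,
        breakpoint_se=np.asarray(psi_se, dtype=float),
        slopes=slopes,
        intercepts=intercepts,
        slope_se=slope_se,
        rss=rss,
        n_obs=len(x),
        converged=converged,
        n_iter=n_iter,
        method=method,
    )


def _interior_range(x: np.ndarray) -> tuple[float, float]:
    xs = np.unique(np.sort(x))
    if len(xs) < 4:
        return float(xs[0]), float(xs[-1])
    # keep breakpoints interior enough that each outer piece holds >= 2 points
    return float(xs[1]), float(xs[-2])


def _grid_search(x, y, k) -> PiecewiseFit:
    """Deterministic grid-search minimizer of the broken-line RSS.

    k = 1 scans a dense 1-D grid exhaustively; k >= 2 runs an
    exhaustive coarse scan over ordered candidate combinations followed
    by per-breakpoint coordinate-descent refinement on dense 1-D grids.
    """
    lo, hi = _interior_range(x)
    if not hi > lo:
        raise PiecewiseFitError(f"not enough distinct x values for {k} breakpoints")

    def rss_at(psi) -> float:
        return _broken_line_ls(x, y, np.asarray(psi))[1]

    from scipy.optimize import minimize_scalar

    def refine_1d(psi: np.ndarray, j: int, left: float, right: float) -> float:
        """Continuous minimum over psi_j in [left, right], others fixed.

        RSS(psi_j) is smooth between data points but kinked at them, so
        each inter-point gap is minimized separately by bounded Brent.
        """
        knots = np.unique(np.concatenate([[left, right], x[(x > left) & (x < right)]]))
        best_p, best_r = psi[j], np.inf
        trial = psi.copy()

        def f(p):
            trial[j] = p
            return rss_at(trial)

        for a, b in zip(knots[:-1], knots[1:]):
            if b - a < 1e-12:
                continue
            res = minimize_scalar(f, bounds=(a, b), method="bounded",
                                  options={"xatol": 1e-10 * max(abs(a), abs(b), 1.0)})
            if res.fun < best_r:
                best_r, best_p = res.fun, float(res.x)
        return best_p

    if k == 1:
        grid = np.linspace(lo, hi, 128)
        p0 = min(grid, key=lambda p: rss_at([p]))
        spacing = (hi - lo) / 127
        best_psi = np.array([p0])
        best_psi[0] = refine_1d(best_psi, 0, max(lo, p0 - 2 * spacing), min(hi, p0 + 2 * spacing))
    else:
        n_c = 40
        while n_c > k and math.comb(n_c, k) > 5000:
            n_c -= 1
        coarse = np.linspace(lo, hi, n_c)
        best_rss, best_psi = np.inf, None
        for combo in itertools.combinations(coarse, k):
            rss = rss_at(combo)
            if rss < best_rss:
                best_rss, best_psi = rss, np.asarray(combo)
        for sweep in range(3):  # refine each breakpoint between its neighbours
            for j in range(k):
                left = lo if j == 0 else best_psi[j - 1]
                right = hi if j == k - 1 else best_psi[j + 1]
                grid = np.linspace(left, right, 48)
                trial = best_psi.copy()

                def rss_j(p):
                    trial[j] = p
                    return rss_at(trial)

                p0 = min(grid, key=rss_j)
                spacing = (right - left) / 47 if right > left else 0.0
                best_psi[j] = p0
                if spacing > 0:
                    best_psi[j] = refine_1d(
                        best_psi, j, max(left, p0 - 2 * spacing), min(right, p0 + 2 * spacing)
                    )
    return _fit_from_psi(x, y, np.sort(best_psi), converged=True, n_iter=0, method="grid")


def _muggeo(x, y, k, damping=0.5, tol=1e-8, max_iter=50) -> PiecewiseFit:
    # initialize at interior quantiles of x
    qs = np.linspace(0, 1, k + 2)[1:-1]
    psi = np.quantile(x, qs)
    x_lo, x_hi = np.min(x), np.max(x)
    last = None
    for it in range(1, max_iter + 1):
        U = [np.clip(x - p, 0.0, None) for p in psi]
        V = [-(x > p).astype(float) for p in psi]
        X = np.column_stack([np.ones_like(x), x] + U + V)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        gamma = beta[2:2 + k]
        v = beta[2 + k:2 + 2 * k]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(gamma) > 1e-300, v / gamma, 0.0)
        new_psi = np.sort(psi + damping * step)
        new_psi = np.clip(new_psi, x_lo + 1e-9, x_hi - 1e-9)
        delta = float(np.max(np.abs(new_psi - psi)))
        psi = new_psi
        if delta < tol:
            # breakpoint SE via the delta method: SE(v_j)/|gamma_j|
            resid = y - X @ beta
            dof = max(len(x) - X.shape[1], 1)
            cov = (resid @ resid / dof) * np.linalg.pinv(X.T @ X)
            se_v = np.sqrt(np.maximum(np.diag(cov)[2 + k:2 + 2 * k], 0.0))
            psi_se = np.where(np.abs(gamma) > 1e-300, se_v / np.abs(gamma), np.nan)
            return _fit_from_psi(x, y, psi, True, it, psi_se=psi_se)
        last = psi
    last_fit = _fit_from_psi(x, y, last, False, max_iter) if last is not None else None
    raise PiecewiseFitError(
        f"broken-line fit did not converge in {max_iter} iterations", last_fit
    )


def fit_piecewise_linear(
    xy: Sequence,
    n_breakpoints: int,
    orientation: Literal["easting_on_northing", "northing_on_easting"] = "easting_on_northing",
    method: Literal["auto", "muggeo", "grid"] = "auto",
) -> PiecewiseFit:
    """Fit a continuous broken line with ``n_breakpoints`` interior breaks.

    ``xy`` is a sequence of Mercator plane points.  By default the
    easting is regressed on the northing, since trans-oceanic migration
    tracks are predominantly meridional and northing is quasi-monotone
    along the track; pass ``orientation="northing_on_easting"`` to swap.

    ``method="muggeo"`` uses damped iterative linearization only and
    raises :class:`PiecewiseFitError` (carrying the last iterate) on
    non-convergence; ``"grid"`` exhaustively searches candidate
    breakpoints; ``"auto"`` tries the iterative fit and falls back to
    the grid search on instances of at most 200 points.
    """
    x, y = _xy_arrays(xy, orientation)
    k = int(n_breakpoints)
    if k < 0:
        raise ValueError("n_breakpoints must be >= 0")
    if len(x) < 2 * (k + 1):
        raise PiecewiseFitError(
            f"{len(x)} points cannot support {k} breakpoints (need >= {2 * (k + 1)})"
        )
    if k == 0:
        return _fit_from_psi(x, y, np.empty(0), converged=True, n_iter=0)
    if method == "grid":
        return _grid_search(x, y, k)
    try:
        return _muggeo(x, y, k)
    except PiecewiseFitError:
        if method == "auto" and len(x) <= 200:
            return _grid_search(x, y, k)
        raise


def select_n_breakpoints(
    xy: Sequence,
    max_k: int,
    orientation: Literal["easting_on_northing", "northing_on_easting"] = "easting_on_northing",
) -> tuple[int, pd.DataFrame]:
    """Choose the breakpoint count in 0..max_k by BIC.

    Returns the chosen k and the full score table (k, rss, bic,
    converged) for audit.  Counts whose fit is infeasible on the data
    are skipped.
    """
    x, y = _xy_arrays(xy, orientation)
    # floor the RSS at numerical-noise scale so an already-perfect fit
    # is never "improved" by extra breakpoints chasing rounding error
    tss = float(np.sum((y - np.mean(y)) ** 2))
    floor = 1e-10 * tss + 1e-300
    rows = []
    fits: dict[int, PiecewiseFit] = {}
    for k in range(int(max_k) + 1):
        try:
            fit = fit_piecewise_linear(xy, k, orientation=orientation)
        except PiecewiseFitError:
            continue
        fits[k] = fit
        n = fit.n_obs
        bic = n * math.log(max(fit.rss, floor) / n) + (3 + 2 * k) * math.log(n)
        rows.append({"k": k, "rss": fit.rss, "bic": bic, "converged": fit.converged})
    if not rows:
        raise PiecewiseFitError("no feasible breakpoint count")
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return best_k, table


def straightness_index(
    points: Sequence, metric: Literal["rhumb_geo", "euclidean_plane"] = "rhumb_geo"
) -> float:
    """Batschelet straightness: endpoint distance / distance travelled.

    With ``metric="rhumb_geo"`` the points are geographic and rhumb-line
    distances are used; with ``"euclidean_plane"`` the points are planar
    2-D coordinates (any units) and chord/chain Euclidean distances are
    used.  The value lies in (0, 1]; 1 means every point sits in order
    on the straight endpoint-to-endpoint line.
    """
    if len(points) < 2:
        raise ValueError("straightness requires at least 2 points")
    if metric == "rhumb_geo":
        total = path_length(points)
        chord = rhumb_distance(points[0], points[-1])
    elif metric == "euclidean_plane":
        arr = np.asarray(
            [(p.easting, p.northing) if isinstance(p, PlanePoint) else tuple(p) for p in points],
            dtype=float,
        )
        steps = np.diff(arr, axis=0)
        total = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
        chord = float(np.hypot(*(arr[-1] - arr[0])))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if total <= 0.0:
        raise ValueError("zero path length: straightness undefined")
    return chord / total


def _circular_mean_sd(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean in [0, 360) and angular deviation sqrt(2(1-R)) in deg."""
    rad = np.radians(angles_deg)
    C, S = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    rbar = float(np.hypot(C, S))
    mean = math.degrees(math.atan2(S, C)) % 360.0
    if mean >= 360.0:
        mean = 0.0
    sd = math.degrees(math.sqrt(max(2.0 * (1.0 - rbar), 0.0)))
    return mean, sd


def _step_mask(fixes: Sequence[GeoFix]) -> np.ndarray:
    """True for consecutive-fix steps no longer than MAX_STEP_GAP_H."""
    dt = np.array(
        [
            (fixes[i + 1].timestamp - fixes[i].timestamp).total_seconds() / 3600.0
            for i in range(len(fixes) - 1)
        ]
    )
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return dt <= MAX_STEP_GAP_H


def summarize_segment(fixes: Sequence[GeoFix]) -> SegmentSummary:
    """Distance, duration, speed, direction and straightness for a segment.

    Per-step speed and bearing statistics use only consecutive fixes at
    most :data:`MAX_STEP_GAP_H` apart, so the overnight duty-cycle gap
    never produces a fictitious slow 12-hour 'step'; distance and
    duration span the whole segment regardless of gaps.
    """
    if len(fixes) < 2:
        raise ValueError("a segment needs at least 2 fixes")
    pts = [f.position for f in fixes]
    dist = path_length(pts)
    duration = (fixes[-1].timestamp - fixes[0].timestamp).total_seconds() / 3600.0
    mask = _step_mask(fixes)
    speeds, bearings = [], []
    for i in range(len(fixes) - 1):
        if not mask[i]:
            continue
        dt = (fixes[i + 1].timestamp - fixes[i].timestamp).total_seconds() / 3600.0
        d = rhumb_distance(pts[i], pts[i + 1])
        speeds.append(d / dt)
        if d > 0:
            bearings.append(rhumb_bearing(pts[i], pts[i + 1]))
    if not speeds:
        raise ValueError("no consecutive-fix steps within the gap limit")
    speeds = np.asarray(speeds)
    if bearings:
        mean_dir, dir_sd = _circular_mean_sd(np.asarray(bearings))
    else:
        mean_dir, dir_sd = math.nan, math.nan
    return SegmentSummary(
        distance_km=dist,
        duration_h=duration,
        speed_kmh=float(np.mean(speeds)),
        speed_sd=float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0,
        direction_deg=mean_dir,
        direction_sd=dir_sd,
        straightness=straightness_index(pts, "rhumb_geo"),
        n_fixes=len(fixes),
    )


def segment_track(
    fixes: Sequence[GeoFix],
    n_breakpoints: int | None = None,
    max_k: int = 4,
    earth_radius_km: float = EARTH_RADIUS_KM,
    orientation: Literal["easting_on_northing", "northing_on_easting"] = "easting_on_northing",
) -> list[TrackSegment]:
    """Split a track into constant-course segments at fitted breakpoints.

    The fixes are Mercator-projected, a broken-line model is fitted
    (breakpoint count fixed, or BIC-chosen up to ``max_k``), and the
    track is cut where consecutive fixes fall on different pieces of the
    fitted model.  The returned segments partition the track: their
    index ranges are contiguous, non-overlapping and exhaustive.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes")
    plane = [mercator_project(f.position, earth_radius_km) for f in fixes]
    if n_breakpoints is None:
        n_breakpoints, _ = select_n_breakpoints(plane, max_k, orientation=orientation)
    fit = fit_piecewise_linear(plane, n_breakpoints, orientation=orientation)
    x = np.array(
        [p.northing if orientation == "easting_on_northing" else p.easting for p in plane]
    )
    piece = np.searchsorted(fit.breakpoints, x, side="right")
    cuts = [0] + [i + 1 for i in range(len(x) - 1) if piece[i + 1] != piece[i]] + [len(x)]
    # merge any cut that would leave a 1-fix segment into its neighbour
    bounds = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if bounds and b - a < 2:
            bounds[-1] = (bounds[-1][0], b)
        else:
            bounds.append((a, b))
    if len(bounds) > 1 and bounds[0][1] - bounds[0][0] < 2:
        bounds[1] = (bounds[0][0], bounds[1][1])
        bounds = bounds[1:]
    bp_coords = tuple(
        PlanePoint(fit.predict(np.array([b]))[0], b)
        if orientation == "easting_on_northing"
        else PlanePoint(b, fit.predict(np.array([b]))[0])
        for b in fit.breakpoints
    )
    segments = []
    for a, b in bounds:
        seg_fixes = tuple(fixes[a:b])
        segments.append(
            TrackSegment(
                fixes=seg_fixes,
                start_index=a,
                stop_index=b,
                summary=summarize_segment(seg_fixes),
                breakpoint_coords=bp_coords,
            )
        )
    return segments


def read_track_csv(path) -> list[GeoFix]:
    """Read a track CSV (timestamp, lat, lon[, alt]) into fixes.

    Timestamps are ISO-8601 and must be strictly increasing; malformed
    rows and ordering violations are reported with their line number.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    fixes: list[GeoFix] = []
    prev_ts = None
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ts = pd.Timestamp(row["timestamp"]).to_pydatetime()
            pos = GeoPoint(float(row["lat"]), float(row["lon"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed track row at line {line}: {exc}") from exc
        if prev_ts is not None and ts <= prev_ts:
            raise ValueError(f"timestamps not strictly increasing at line {line}")
        prev_ts = ts
        alt = float(row["alt"]) if "alt" in df.columns and pd.notna(row.get("alt")) else None
        fixes.append(GeoFix(ts, pos, alt))
    return fixes


_SUMMARY_COLUMNS = [
    "bird",
    "segment",
    "start_lat",
    "start_lon",
    "end_lat",
    "end_lon",
    "n_fixes",
    "distance_km",
    "duration_h",
    "speed_kmh",
    "speed_sd",
    "direction_deg",
    "direction_sd",
    "straightness",
]


def write_summary_table(
    segments: Sequence[TrackSegment],
    path=None,
    bird: str = "",
) -> pd.DataFrame:
    """Render segments as a summary table (one row per segment).

    Column order mirrors the published per-segment summaries so the
    output is directly comparable with the packaged reference tables.
    Writes CSV when ``path`` is given; always returns the DataFrame.
    """
    rows = []
    for j, seg in enumerate(segments, start=1):
        s = seg.summary
        rows.append(
            {
                "bird": bird,
                "segment": j,
                "start_lat": seg.fixes[0].position.lat,
                "start_lon": seg.fixes[0].position.lon,
                "end_lat": seg.fixes[-1].position.lat,
                "end_lon": seg.fixes[-1].position.lon,
                "n_fixes": s.n_fixes,
                "distance_km": s.distance_km,
                "duration_h": s.duration_h,
                "speed_kmh": s.speed_kmh,
                "speed_sd": s.speed_sd,
                "direction_deg": s.direction_deg,
                "direction_sd": s.direction_sd,
                "straightness": s.straightness,
            }
        )
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df
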