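"""Shared fixtures: a dipole world, track builders, drift-step pools."""

from __future__ import annotations

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from natalnav.geodesy import GeoPoint
from natalnav.magframe import DipoleModel, NatalFrame
from natalnav.synthdata import TruthManifest, make_track, make_world
from natalnav.trackseg import GeoFix, summarize_segment
from natalnav.winddrift import decompose_step

T0 = datetime(2009, 9, 14, 13, 0, 0)


@pytest.fixture(scope="session")
def dipole() -> DipoleModel:
    return DipoleModel()


@pytest.fixture(scope="session")
def nest_frame(dipole) -> NatalFrame:
    return NatalFrame.from_field(dipole, GeoPoint(41.47, -70.62))


def straight_fixes(
    bearing_deg: float,
    hours: int,
    speed_kmh: float = 45.0,
    start: tuple[float, float] = (41.4, -70.6),
    t0: datetime = T0,
) -> list[GeoFix]:
    """Hourly fixes along a constant local bearing (flat-step integration)."""
    lat, lon = start
    fixes = [GeoFix(t0, GeoPoint(lat, lon))]
    for h in range(1, hours + 1):
        lat += speed_kmh * math.cos(math.radians(bearing_deg)) / 111.195
        lon += speed_kmh * math.sin(math.radians(bearing_deg)) / (
            111.195 * math.cos(math.radians(lat))
        )
        fixes.append(GeoFix(t0 + timedelta(hours=h), GeoPoint(lat, lon)))
    return fixes


def behaviour_steps(alpha: float, behavior: str, n_tracks: int = 12, seed0: int = 0):
    """Pooled decomposed steps from seeded behaviour-controlled tracks.

    Decomposition uses the generator's recorded hourly-mean winds (the
    exact winds that displaced the bird) so the estimator is validated
    free of wind-interpolation error.  Returns (steps, group labels).
    """
    steps, groups = [], []
    for i in range(n_tracks):
        world = make_world(seed=seed0 + i)
        start = GeoFix(T0, GeoPoint(42.0, -72.0 + (i % 5) * 2.5))
        manifest = TruthManifest(
            behavior=behavior, alpha=alpha, courses=[(0.0, 185.0 + 2 * (i % 4))]
        )
        fixes, winds = make_track(world, manifest, start, 30, return_winds=True)
        mu = summarize_segment(fixes).direction_deg
        for j in range(len(fixes) - 1):
            steps.append(decompose_step(fixes[j], fixes[j + 1], winds[j], mu))
            groups.append(i)
    return steps, groups


def two_piece_instance(seed: int, n: int = 50, brk: float = 3000.0):
    """Planar two-piece broken line: slopes -0.2 / +0.6, Gaussian σ=1 km.

    Returns points in (easting, northing) orientation for the default
    easting-on-northing regression.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 6000.0, n)
    y = np.where(x < brk, -0.2 * x, -0.2 * brk + 0.6 * (x - brk))
    y = y + rng.normal(0.0, 1.0, n)
    return list(zip(y, x))
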