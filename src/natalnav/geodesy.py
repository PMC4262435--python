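"""Spherical-Earth rhumb-line (loxodrome) geodesy and Mercator projection.

A rhumb line is the path of constant true bearing on the sphere; it maps
to a straight line under the Mercator projection, which is why constant
course movement analysis is most natural in this geometry.  All angles
are degrees, all distances kilometres.  The Earth model is a sphere of
radius ``EARTH_RADIUS_KM`` (IUGG mean radius); an alternative radius can
be passed to every function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "PlanePoint",
    "rhumb_distance",
    "rhumb_bearing",
    "mercator_project",
    "mercator_unproject",
    "path_length",
]

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

# Below this |Δψ| a rhumb step is treated as purely east-west to avoid 0/0.
_MERIDIONAL_EPS = 1e-12


def _normalize_lon(lon: float) -> float:
    """Wrap longitude into (-180, 180]."""
    lon = math.fmod(lon, 360.0)
    if lon <= -180.0:
        lon += 360.0
    elif lon > 180.0:
        lon -= 360.0
    return lon


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position in degrees.

    Latitude must lie in [-90, 90]; longitude is normalized to
    (-180, 180] on construction.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not math.isfinite(self.lon):
            raise ValueError("longitude must be finite")
        object.__setattr__(self, "lon", _normalize_lon(self.lon))


@dataclass(frozen=True)
class PlanePoint:
    """A Mercator plane position: easting/northing in kilometres."""

    easting: float
    northing: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.easting) and math.isfinite(self.northing)):
            raise ValueError("plane coordinates must be finite")


def _as_geopoint(p) -> GeoPoint:
    if isinstance(p, GeoPoint):
        return p
    lat, lon = p
    return GeoPoint(float(lat), float(lon))


def _check_not_pole(p: GeoPoint) -> None:
    if abs(p.lat) >= 90.0:
        raise ValueError("rhumb-line geometry is undefined at the poles")


def _delta_lon_deg(lon1: float, lon2: float) -> float:
    """Signed longitude difference in degrees, shortest sense (-180, 180]."""
    d = math.fmod(lon2 - lon1, 360.0)
    if d > 180.0:
        d -= 360.0
    elif d <= -180.0:
        d += 360.0
    return d


def _isometric_lat(lat_rad: float) -> float:
    """Mercator isometric latitude ψ = ln tan(π/4 + φ/2)."""
    if lat_rad == 0.0:
        return 0.0
    return math.log(math.tan(math.pi / 4.0 + lat_rad / 2.0))


def rhumb_distance(a, b, radius: float = EARTH_RADIUS_KM) -> float:
    """Length in km of the loxodrome joining ``a`` to ``b``.

    Symmetric, nonnegative, and zero only for coincident points.  The
    longitude difference is taken in the shortest sense, so a track is
    assumed not to wrap more than half-way round the Earth in one step.
    """
    a = _as_geopoint(a)
    b = _as_geopoint(b)
    _check_not_pole(a)
    _check_not_pole(b)
    lat1, lat2 = math.radians(a.lat), math.radians(b.lat)
    dlat = lat2 - lat1
    dlon = math.radians(_delta_lon_deg(a.lon, b.lon))
    dpsi = _isometric_lat(lat2) - _isometric_lat(lat1)
    if abs(dpsi) > _MERIDIONAL_EPS:
        q = dlat / dpsi
    else:
        q = math.cos(lat1)
    return math.hypot(dlat, q * dlon) * radius


def rhumb_bearing(a, b) -> float:
    """Constant true bearing in degrees [0, 360) of the loxodrome a→b.

    Raises ``ValueError`` for coincident points, where the bearing is
    undefined.  Meridional pairs return exactly 0.0 or 180.0.
    """
    a = _as_geopoint(a)
    b = _as_geopoint(b)
    _check_not_pole(a)
    _check_not_pole(b)
    dlon_deg = _delta_lon_deg(a.lon, b.lon)
    if a.lat == b.lat and dlon_deg == 0.0:
        raise ValueError("bearing undefined for coincident points")
    if dlon_deg == 0.0:
        return 0.0 if b.lat > a.lat else 180.0
    dpsi = _isometric_lat(math.radians(b.lat)) - _isometric_lat(math.radians(a.lat))
    theta = math.degrees(math.atan2(math.radians(dlon_deg), dpsi)) % 360.0
    return 0.0 if theta >= 360.0 else theta


def mercator_project(p, radius: float = EARTH_RADIUS_KM) -> PlanePoint:
    """Spherical Mercator projection, easting/northing in km.

    The equator maps to northing 0 and the Greenwich meridian to
    easting 0.  Latitudes of ±90° are outside the projection's domain.
    """
    p = _as_geopoint(p)
    _check_not_pole(p)
    easting = radius * math.radians(p.lon)
    northing = radius * _isometric_lat(math.radians(p.lat))
    return PlanePoint(easting, northing)


def mercator_unproject(q: PlanePoint, radius: float = EARTH_RADIUS_KM) -> GeoPoint:
    """Inverse spherical Mercator projection."""
    if not isinstance(q, PlanePoint):
        q = PlanePoint(*q)
    lon = math.degrees(q.easting / radius)
    lat = math.degrees(2.0 * math.atan(math.exp(q.northing / radius)) - math.pi / 2.0)
    return GeoPoint(lat, lon)


def path_length(points: Sequence | Iterable, radius: float = EARTH_RADIUS_KM) -> float:
    """Total rhumb-line distance along an ordered sequence of points, km.

    The path is the chain of loxodrome steps between consecutive points;
    it is always at least as long as the single loxodrome joining the
    endpoints.
    """
    pts = [_as_geopoint(p) for p in points]
    if len(pts) < 2:
        raise ValueError("path_length requires at least 2 points")
    return float(
        np.sum([rhumb_distance(pts[i], pts[i + 1], radius) for i in range(len(pts) - 1)])
    )
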