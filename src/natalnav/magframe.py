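"""Seven-element geomagnetic algebra and the nest-origin coordinate frame.

The geomagnetic field at a point is described by seven elements: the
Cartesian components X (geographic north), Y (east), Z (vertical,
positive down) and the derived total intensity F, horizontal intensity
H, declination D (positive east of true north) and inclination I
(positive down).  The module provides the exact algebra between the
two representations, two pluggable field models — an analytic tilted
centred dipole and a bilinear interpolator over a pre-evaluated element
grid (the export of a reference model such as WMM/IGRF/EMM) — and the
natal-frame transformation: the rigid rotation-and-translation that
re-expresses {X, Y, Z} in a coordinate space whose origin is the
magnetic field vector at an animal's nest site.

In the natal frame, x_T points along the nest's field line, y_T is the
horizontal-perpendicular axis and z_T the vertical-perpendicular axis;
the nest itself maps to (0, 0, 0).  A bird's displacement from home
therefore appears as a trajectory in the y_T-z_T plane, the plane
perpendicular to the nest's field line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date

import numpy as np

from .geodesy import GeoPoint

__all__ = [
    "MagElements",
    "NatalFrame",
    "NatalCoords",
    "elements_from_xyz",
    "xyz_from_elements",
    "natal_transform",
    "natal_untransform",
    "DipoleModel",
    "dipole_field",
    "ElementGrid",
    "gridded_field",
]


@dataclass(frozen=True)
class MagElements:
    """The seven magnetic field elements (nT for intensities, degrees
    for angles; Z and I positive downward, D positive east)."""

    F: float
    I: float
    D: float
    H: float
    X: float
    Y: float
    Z: float


def elements_from_xyz(X: float, Y: float, Z: float) -> MagElements:
    """Derive all seven elements from the Cartesian components.

    Declination is undefined where the horizontal field vanishes
    (at a magnetic pole); that raises ``ValueError``.
    """
    H = math.hypot(X, Y)
    F = math.hypot(H, Z)
    if H == 0.0:
        raise ValueError("horizontal field is zero: declination undefined")
    D = math.degrees(math.atan2(Y, X))
    I = math.degrees(math.atan2(Z, H))
    return MagElements(F=F, I=I, D=D, H=H, X=X, Y=Y, Z=Z)


def xyz_from_elements(F: float, I: float, D: float) -> tuple[float, float, float]:
    """Cartesian components from intensity, inclination and declination."""
    if F <= 0.0:
        raise ValueError("total intensity must be positive")
    H = F * math.cos(math.radians(I))
    return (
        H * math.cos(math.radians(D)),
        H * math.sin(math.radians(D)),
        F * math.sin(math.radians(I)),
    )


@dataclass(frozen=True)
class NatalFrame:
    """The nest-site field that anchors the transformed coordinate space.

    ``phi`` is the nest declination, ``theta`` the nest inclination and
    ``F_nest`` the nest total intensity, all evaluated at the nest on
    the reference date (May 1 of the hatch year by convention, when the
    bird was in the egg)."""

    phi: float
    theta: float
    F_nest: float
    nest: GeoPoint | None = None
    reference_date: date | None = None

    @classmethod
    def from_field(cls, field, nest: GeoPoint, reference_date: date | None = None) -> "NatalFrame":
        """Build the frame by evaluating a field model at the nest."""
        el = field.elements(nest)
        return cls(
            phi=el.D, theta=el.I, F_nest=el.F, nest=nest, reference_date=reference_date
        )


@dataclass(frozen=True)
class NatalCoords:
    """Coordinates in the nest-origin frame (nT)."""

    x_T: float
    y_T: float
    z_T: float


def _rotation(frame: NatalFrame) -> np.ndarray:
    phi = math.radians(frame.phi)
    theta = math.radians(frame.theta)
    # horizontal rotation about the vertical axis by the nest declination
    Rz = np.array(
        [
            [math.cos(phi), math.sin(phi), 0.0],
            [-math.sin(phi), math.cos(phi), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    # vertical rotation about the new horizontal y' axis by the nest inclination
    Ry = np.array(
        [
            [math.cos(theta), 0.0, math.sin(theta)],
            [0.0, 1.0, 0.0],
            [-math.sin(theta), 0.0, math.cos(theta)],
        ]
    )
    return Ry @ Rz


def natal_transform(xyz, frame: NatalFrame) -> NatalCoords:
    """Map field Cartesian coordinates into the nest-origin frame.

    Three sequential rigid motions: rotate horizontally about the
    vertical axis by the nest declination φ, rotate vertically about
    the new y' axis by the nest inclination θ, then translate along the
    resulting x'' axis by the nest intensity F.  The nest's own field
    vector maps exactly to the origin, and the rotations preserve the
    Euclidean norm, so (x_T + F_nest)² + y_T² + z_T² = F² at every
    location.
    """
    v = np.asarray(xyz, dtype=float)
    out = _rotation(frame) @ v
    return NatalCoords(x_T=out[0] - frame.F_nest, y_T=out[1], z_T=out[2])


def natal_untransform(coords: NatalCoords, frame: NatalFrame) -> tuple[float, float, float]:
    """Exact inverse of :func:`natal_transform`."""
    v = np.array([coords.x_T + frame.F_nest, coords.y_T, coords.z_T])
    out = _rotation(frame).T @ v
    return float(out[0]), float(out[1]), float(out[2])


@dataclass(frozen=True)
class DipoleModel:
    """A centred tilted dipole: equatorial surface intensity ``B0`` (nT)
    and the geographic position of the north geomagnetic pole.

    Closed forms on the sphere, with λ_m the magnetic latitude:
    F = B0·√(1 + 3 sin²λ_m), tan I = 2 tan λ_m, and declination given
    by the local direction of magnetic north (the great-circle bearing
    to the geomagnetic pole).  Defaults approximate the recent-epoch
    north geomagnetic pole.
    """

    B0: float = 30000.0
    pole: GeoPoint = GeoPoint(80.0, -72.0)

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")

    def magnetic_latitude(self, p: GeoPoint) -> float:
        """Magnetic latitude in degrees: 90° minus colatitude from pole."""
        lat, lon = math.radians(p.lat), math.radians(p.lon)
        plat, plon = math.radians(self.pole.lat), math.radians(self.pole.lon)
        cosc = math.sin(lat) * math.sin(plat) + math.cos(lat) * math.cos(plat) * math.cos(
            lon - plon
        )
        return 90.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosc))))

    def xyz(self, p: GeoPoint) -> tuple[float, float, float]:
        lam = math.radians(self.magnetic_latitude(p))
        H = self.B0 * math.cos(lam)
        Z = 2.0 * self.B0 * math.sin(lam)
        lat, lon = math.radians(p.lat), math.radians(p.lon)
        plat, plon = math.radians(self.pole.lat), math.radians(self.pole.lon)
        # great-circle initial bearing to the geomagnetic pole = declination
        dlon = plon - lon
        yb = math.sin(dlon) * math.cos(plat)
        xb = math.cos(lat) * math.sin(plat) - math.sin(lat) * math.cos(plat) * math.cos(dlon)
        if abs(yb) < 1e-300 and abs(xb) < 1e-300:
            D = 0.0  # at the pole itself the horizontal direction degenerates
        else:
            D = math.degrees(math.atan2(yb, xb))
        return (H * math.cos(math.radians(D)), H * math.sin(math.radians(D)), Z)

    def elements(self, p: GeoPoint) -> MagElements:
        return elements_from_xyz(*self.xyz(p))


def dipole_field(p: GeoPoint, model: DipoleModel | None = None) -> tuple[float, float, float]:
    """Cartesian (X, Y, Z) of the tilted dipole at ``p`` (nT)."""
    return (model or DipoleModel()).xyz(p)


class ElementGrid:
    """Bilinear interpolator over a pre-evaluated field-element grid.

    The grid stores the Cartesian components X, Y, Z on regular lat/lon
    axes (e.g. exported from a spherical-harmonic reference model); the
    derived elements F, H, D, I are always recomputed from interpolated
    X, Y, Z rather than interpolated directly, which keeps the element
    identities (H = F cos I etc.) exact at every query point.
    """

    def __init__(self, lats, lons, X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
                 epoch: date | None = None):
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        self.epoch = epoch
        shape = (len(self.lats), len(self.lons))
        self.X, self.Y, self.Z = (np.asarray(a, dtype=float) for a in (X, Y, Z))
        for a in (self.X, self.Y, self.Z):
            if a.shape != shape:
                raise ValueError(f"component arrays must have shape {shape}")
        from scipy.interpolate import RegularGridInterpolator

        axes = (self.lats, self.lons)
        self._interp = [
            RegularGridInterpolator(axes, a, bounds_error=True) for a in (self.X, self.Y, self.Z)
        ]

    @classmethod
    def from_field(cls, field, lats, lons, epoch: date | None = None) -> "ElementGrid":
        """Tabulate any field model (e.g. a dipole) onto a grid."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        X = np.empty((len(lats), len(lons)))
        Y = np.empty_like(X)
        Z = np.empty_like(X)
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                X[i, j], Y[i, j], Z[i, j] = field.xyz(GeoPoint(la, lo))
        return cls(lats, lons, X, Y, Z, epoch=epoch)

    @classmethod
    def from_csv(cls, path, epoch: date | None = None) -> "ElementGrid":
        import pandas as pd

        df = pd.read_csv(path)
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        shape = (len(lats), len(lons))
        df = df.sort_values(["lat", "lon"])
        if len(df) != shape[0] * shape[1]:
            raise ValueError("element CSV does not describe a complete regular grid")
        return cls(
            lats,
            lons,
            df["X"].to_numpy().reshape(shape),
            df["Y"].to_numpy().reshape(shape),
            df["Z"].to_numpy().reshape(shape),
            epoch=epoch,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        pd.DataFrame(
            {
                "lat": la.ravel(),
                "lon": lo.ravel(),
                "X": self.X.ravel(),
                "Y": self.Y.ravel(),
                "Z": self.Z.ravel(),
            }
        ).to_csv(path, index=False)

    def xyz(self, p: GeoPoint) -> tuple[float, float, float]:
        pt = np.array([[p.lat, p.lon]])
        return tuple(float(f(pt)[0]) for f in self._interp)

    def elements(self, p: GeoPoint) -> MagElements:
        return elements_from_xyz(*self.xyz(p))


def gridded_field(p: GeoPoint, grid: ElementGrid) -> MagElements:
    """All seven elements at ``p`` by bilinear interpolation of X, Y, Z."""
    return grid.elements(p)
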