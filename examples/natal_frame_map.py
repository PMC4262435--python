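"""Compare coordinate spaces for bicoordinate positional orientation.

Builds the 0.5° survey grid over the western Atlantic domain in a
dipole magnetic world and contrasts the classic intensity-inclination
(F-I) space with the nest-origin transformed magnetic (y_T-z_T) plane:
the former is almost perfectly autocorrelated (useless as a 2-D map),
the latter is not.
"""

import numpy as np

from natalnav.geodesy import GeoPoint
from natalnav.magframe import DipoleModel, NatalFrame, natal_transform
from natalnav.spacecompare import build_grid, fit_polynomial_hz

dipole = DipoleModel()
nest = GeoPoint(41.47, -70.62)
frame = NatalFrame.from_field(dipole, nest)
print(
    f"Natal frame at the nest: declination {frame.phi:+.2f}°, "
    f"inclination {frame.theta:.2f}°, intensity {frame.F_nest:.0f} nT"
)

grid = build_grid((20, 42), (-78, -67), 0.5)
els = [dipole.elements(p) for p in grid]
F = np.array([e.F for e in els])
incl = np.array([e.I for e in els])
hz = np.array([(e.H, e.Z) for e in els])
yz = np.array(
    [(lambda c: (c.y_T, c.z_T))(natal_transform(dipole.xyz(p), frame)) for p in grid]
)

print(f"Survey grid: {len(grid)} nodes at 0.5° spacing")
print(f"corr(F, I) over the grid:      {np.corrcoef(F, incl)[0, 1]:+.4f}")
print(f"4th-order H-Z polynomial r^2:  {fit_polynomial_hz(hz, 4).r2:.5f}")
print(f"corr(y_T, z_T) over the grid:  {np.corrcoef(yz[:, 0], yz[:, 1])[0, 1]:+.4f}")
print(
    "\nF and I are near-perfectly correlated over this domain — every track "
    "collapses onto one curve, so F-I cannot localize a bird here.  The "
    "nest-origin y_T-z_T coordinates are nearly uncorrelated and retain "
    "two-dimensional resolution."
)
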