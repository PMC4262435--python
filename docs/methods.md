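# Methods

This note documents the models, conventions and numerical choices behind
`natalnav`, in the order the pipeline applies them.

## Geodesy

The Earth is a sphere of radius 6371.0088 km (the IUGG mean radius).  All
between-fix distances and bearings are rhumb-line (loxodrome) quantities:
the loxodrome is the constant-bearing path, straight under the Mercator
projection, which is the natural geometry for "constant course" analysis.
Geodesic (great-circle/ellipsoidal) distances are deliberately out of
scope.  Longitude differences are taken in the shortest sense (−180°, 180°];
the study domain never approaches the antimeridian.  Near-meridional steps
(|Δψ| < 1e−12) fall back to the east–west limit q = cos φ to avoid 0/0, and
poles are outside the domain of every operation.  On the reference segment
used for validation (a published 1572.1 km constant-course movement), this
Earth model reproduces the printed straightness ratio to 4 decimals and the
endpoint rhumb distance to ≲0.03%; the residual ~0.4 km disagreement in the
"excess over a straight rhumb line" is within the slack expected from the
unstated geodesy convention of the original analysis.

## Track model and segmentation

A track is a strictly time-ordered sequence of GPS fixes.  The tags emulated
here record hourly positions over a 12 h on / 12 h off duty cycle, so
per-step statistics (speeds, bearings) are computed only between consecutive
fixes ≤ 2 h apart; segment-level distance and duration span gaps.

Segmentation fits a continuous broken-line model to Mercator coordinates.
The default orientation regresses easting on northing because the study
tracks are predominantly meridional, making northing quasi-monotone along
the track; a flag swaps the orientation.  The fitter is a damped iterative
linearization (breakpoint update ψ ← ψ + 0.5·v/γ, tolerance 1e−8 km, max 50
iterations) in the style of the broken-line estimators used in regression
packages, with the breakpoint standard error SE(ψ) = SE(v)/|γ| by the delta
method.  On instances of ≤ 200 points a deterministic grid-search fallback
(and independent oracle) is available: a dense 1-D scan for one breakpoint,
or a bounded exhaustive scan (≤ 5000 combinations) with coordinate-descent
refinement for more, each candidate refined by bounded Brent minimization
within inter-point gaps — the RSS(ψ) surface is smooth between data points
but kinked at them, and the continuous optimum is sharp because the
breakpoint is pinned by the intersection of the two fitted lines.  The
iterative fit and the oracle agree in RSS to ~1e−11 relative on 50-point
two-piece instances.

The number of breakpoints is chosen by BIC over 0..max_k with 3 + 2k
parameters (two line coefficients, σ, and a position plus slope change per
breakpoint).  The RSS entering the BIC is floored at 1e−10 of the total sum
of squares so that an already-exact fit is never "improved" by extra
breakpoints chasing rounding noise.

Straightness is Batschelet's index: endpoint distance over path distance,
rhumb-line in geographic space, Euclidean in any planar trace.  The circular
spread reported with mean track directions is the angular deviation
√(2(1−R̄)) in degrees (the ±1σ convention of the source tables is unstated;
this is the standard circular analogue).

## Wind-triangle decomposition

Winds are 10 m U10/V10 components in km/h on a regular (time, lat, lon)
grid, sampled by trilinear interpolation.  By default the wind for a step is
sampled at the step's temporal and spatial midpoint: an hourly displacement
integrates the wind over the whole hour, and midpoint sampling is the least
biased single-point summary (sampling at the starting fix measurably
attenuates the drift-regression slope — about 15% under full drift in the
synthetic world).  Start-fix sampling remains available.

Sign conventions: bearings are degrees clockwise from true north;
perpendicular components are positive to the right of the mean track
direction μ; the drift angle δ = groundtrack bearing − μ is wrapped to
(−180°, 180°].  The decomposition enforces g = h + w exactly (h is obtained
by vector subtraction), and the identities f_m = |g| cos δ, p_m = |g| sin δ,
a_m = f_m − t_w hold by construction.

The three drift regressions (p_m~p_w, f_m~t_w, a_m~t_w) are ordinary least
squares with the standard regression F-test (df 1, n−2).  When steps are
pooled across segments, each segment's own μ absorbs that segment's mean
drift, so the pooled slope is structurally attenuated toward 0 (measured
0.83 instead of 1.0 under full drift); an optional within-segment
(fixed-effects) estimator demeans per segment and reduces the residual df by
the number of absorbed intercepts.  The naive pooled fit remains the
default because it mirrors the conventional procedure; the fixed-effects
fit is what the ground-truth recovery checks use.

Overcompensation is the fraction of steps with sign(p_m) ≠ sign(p_w),
excluding exact zeros from both numerator and denominator.

## Circular statistics

The mean direction is the resultant-vector mean; its 95% interval is a
bootstrap percentile interval (default 1000 resamples, seeded) on the
wrapped deviations of resampled means from the point estimate, with the von
Mises concentration κ estimated from R̄ by the Best–Fisher approximation
(small-sample corrected).  The Watson two-sample U² statistic is computed
from pooled empirical CDF differences with multiplicity weighting (midrank
equivalent) and is exactly invariant to common rotations.  Its asymptotic
p-value uses the limiting tail P(U² > u) = 2·exp(−2π²u), which reproduces
the standard critical values 0.152/0.187/0.268 at α = 0.10/0.05/0.01 and is
applied only with ≥ 8 observations per sample; a seeded permutation p-value
(default 9999 reassignments) covers smaller samples.  Simulated type-I error
at α = 0.05 with n = 20 per sample is ~0.046–0.052.

## Geomagnetic coordinates and the natal frame

The seven field elements obey F² = X² + Y² + Z², H = F cos I, Z = F sin I,
X = H cos D, Y = H sin D, with Z and I positive down and D positive east.
Declination is undefined where H = 0 (a field pole) and that is an error,
not a silent default.

Field models are pluggable through a two-method protocol (`xyz`,
`elements`):

* **Tilted centred dipole** — closed forms on the sphere with magnetic
  latitude λ_m measured from the geomagnetic pole (default B0 = 30000 nT,
  pole at 80°N, 72°W, approximating the recent-epoch pole): F = B0√(1+3
  sin²λ_m), tan I = 2 tan λ_m, and declination equal to the great-circle
  bearing of the geomagnetic pole (the direction of magnetic north for an
  axisymmetric field).
* **Element grid** — bilinear interpolation of X, Y, Z on regular lat/lon
  axes, intended to carry the pre-evaluated output of a spherical-harmonic
  reference model (WMM/IGRF/EMM); evaluating such models is out of scope.
  Derived elements are always recomputed from interpolated X, Y, Z, never
  interpolated directly, which keeps the element identities exact and keeps
  interpolated inclination within 0.01° of a smooth model between nodes.

The natal transformation applies three rigid motions to the location's
(X, Y, Z): a horizontal rotation about the vertical axis by the nest
declination φ, a vertical rotation about the new y′ axis by the nest
inclination θ, and a translation along the resulting x″ axis by the nest
intensity F.  The rotation sign convention is pinned by the defining
property that the nest's own field vector maps exactly to the origin (and
by norm preservation before translation); both are enforced to 1e−9
relative in the tests.  The frame is evaluated at the nest on May 1 of the
hatch year; secular variation over a single tracking season is ignored,
which is safe for birds under one year old.  x_T points along the nest's
field line; y_T and z_T span the perpendicular plane, where analysis is
restricted (3-D coordinates are still emitted).

## Cross-space comparison

Traces of the same segment are produced in four spaces: Mercator (km), F–I
polar, its Cartesian H–Z equivalent (nT), and y_T–z_T (nT).  Polynomial
trend fits regress the second coordinate on powers of the first (Z on H by
default; flag to swap).  Because nT-scale abscissae raised to the 4th power
are catastrophically ill-conditioned, fitting is performed on a
centred/scaled regressor and the coefficients and covariance are mapped
back to the raw basis exactly.  Polynomial order is selected by sequential
nested-model F-tests (recommended order = highest order whose gain is
significant at α = 0.05); a zero-residual larger model is reported as
saturated rather than given a fabricated F.

Pairwise segment comparison computes, per coefficient j, the two-sample
statistic t = (b₁ⱼ − b₂ⱼ)/√(SE₁ⱼ² + SE₂ⱼ²) with df = n₁ + n₂ − 2(k+1), and a
pair is "significantly different" when any coefficient differs at α = 0.05
with no multiplicity correction — matching the conventional multiple-ANOVA
usage for this analysis; a Bonferroni option (α divided by the number of
coefficients) is provided but off by default.  Traces too short for the
model are excluded with a warning and listed in the result.

## Synthetic worlds

The generator is first-class, seeded, and bit-reproducible: every output is
a pure function of (parameters, seed).

* **Wind** — each component is a mean flow plus a sum of 16 random Fourier
  harmonics with lognormally scattered wavelengths (median 600 km) and
  periods (median 18 h), a realistic synoptic scale for the region.  The
  two free magnitudes are calibrated by a damped fixed-point loop so the
  domain speed statistics match the observed regime: mean 27.3 km/h,
  σ 13.5 km/h, prevailing flow out of the northeast; generated speeds span
  roughly 0–85 km/h, covering the observed 2–70 km/h range.  The field is
  not divergence-constrained — it emulates the statistics of mesoscale
  winds, not their dynamics.
* **Tracks** — integrated at 6-minute substeps with hourly fixes.  Full
  compensation re-solves the wind triangle each substep so the groundtrack
  holds the intended course; the default airspeed policy holds the forward
  ground speed at 45 km/h (the bird raises its airspeed into headwinds, the
  behaviour seen in the tracked birds), with a "hold airspeed" alternative
  and a 90 km/h airspeed cap whose binding substeps are recorded in the
  manifest as residual drift.  Full drift holds the heading fixed at the
  intended course (airspeed 40 km/h) and lets the wind displace the track;
  partial(α) mixes the two heading solutions linearly, which makes the
  expected slope of p_m on p_w exactly 1−α.  A per-hour isotropic heading
  jitter (σ = 2 km/h) represents behavioural imperfection; without it
  generated tracks are exactly model-deterministic and regression standard
  errors collapse to rounding noise.  An optional 12 h duty cycle thins the
  emitted fixes while the integration continues through the gap.
* **Ground truth** — the manifest records the intended courses (later
  course starts are the true breakpoints), the compensation coefficient,
  and the airspeed policy; `make_track` can also return the substep-mean
  wind of every hour, the exact wind that displaced the bird, which the
  validation suites use to score the estimators free of wind-interpolation
  error.

What the synthetic world does not emulate: GPS position error (±18 m is
negligible at hourly 40 km steps), thermal soaring and altitude-dependent
winds, landmass avoidance, and real geomagnetic structure (crustal
anomalies, secular variation).  Passing tests therefore demonstrate that
the estimators recover known behaviour under realistic kinematics and wind
statistics — not that any particular real dataset would yield the same
regression coefficients.

## Validation problem sizes

The checked properties run at deliberately modest, seeded sizes chosen to
make the statistics sharp: behaviour recovery pools ~1015 hourly steps from
35 tracks of 30 h per compensation level (slope within 2 SE of 1−α for
α ∈ {0, 0.5, 1}); Watson calibration uses 2000 null simulations at n = 20
per sample; breakpoint recovery uses 20 seeded 50-point two-piece tracks
(σ = 1 km noise, slopes −0.2/+0.6) scored within 3 SE against the
grid-search oracle; natal-frame geometry is checked at 10 nest sites with
random in-domain probes; the coordinate-space degeneracy contrast uses the
full 1035-node 0.5° survey grid and 25 noiseless radiating segments.

## Known limitations

* The dipole world's F–I autocorrelation (r ≈ 0.999) and H–Z quartic fit
  (r² ≈ 1.0) are cleaner than any real crustal-field region; with a real
  element grid the same code reports correspondingly rougher values.
* The per-segment mean-direction convention makes pooled drift regressions
  conservative (attenuated toward no-drift); use the fixed-effects option
  when segments experience systematically different winds.
* The broken-line fitter assumes the regressor is quasi-monotone along the
  track; loops or strongly zonal tracks need the swapped orientation or a
  different segmentation variable.
* Bootstrap circular CIs undercover slightly for very small samples
  (n < 10); the coverage check is run at n = 500.
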