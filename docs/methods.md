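# Methods

## Field model

The package treats every channel measurement as a sample of a curl- and
divergence-free magnetic field, expanded in gradients of solid harmonics
about an origin.  Real spherical harmonics `S_lm` are used throughout; the
associated Legendre functions carry the Condon–Shortley phase and the
normalization constant carries a matching `(−1)^m`, so the two signs cancel
and the family is orthonormal on the sphere (verified by Gauss–Legendre ×
trapezoid quadrature to 1e-6 for all pairs up to l = 6).  The azimuth uses
the four-quadrant arctangent; a two-quadrant `atan(y/x)` would flip odd-m
harmonics for x < 0.  Physical prefactors (−μ0 and the dipole scale) are
absorbed into the expansion coefficients: every reported metric is a
variance *ratio* and is invariant to per-column scaling of the bases.

Truncation starts at l = 1 (an l = 0 internal term would be a magnetic
monopole) and gives `L² + 2L` terms at order `L`, ordered l-ascending,
m-ascending within l — so the order-L basis is always the leading block of
any higher-order basis, and coefficient vectors are portable across runs.

### Evaluation

Production evaluation never touches spherical angles.  Each real solid
harmonic is factored as `a_lm · A_lm(z, r²) · T_m(x, y)` where `A_lm` is
the polynomial part of the Legendre function and `T_m` is the real or
imaginary part of `(x + iy)^m`; both satisfy three-term recurrences whose
z-, and r²-derivatives are propagated through the same recurrences.  Values
and Cartesian gradients are therefore exact polynomials (times a power of
r for the irregular family), finite at the coordinate poles, and agree
with central finite differences to better than 1e-6 relative at random
points (tested to l = 8; the printed closed-form Legendre sum serves as an
independent oracle in the tests).

### Conditioning

Irregular-harmonic columns span ~17 orders of magnitude between l = 1 and
l = 15 at head scale.  All subspace, projector and leverage computations
normalize basis columns to unit norm before the SVD; the subspace is
unchanged and the rank truncation (singular values below 1e-10 of the
largest) then measures geometry rather than units.  Effective ranks are
recorded on the returned objects, and a rank-deficient external basis
(regressor count at or beyond the channel count — the statistical limit)
warns instead of failing.

## Synthetic head

No subject data are used.  Defaults, all in metres:

| quantity | default | rationale |
|---|---|---|
| scalp semi-axes | (0.075, 0.095, 0.085) | adult head half-width/length/height |
| scalp centre | (0, 0, −0.02) | origin offset so vertex radii vary |
| helmet cut plane | z = −0.075 | coverage down the sides of the head |
| cortex base radius | 0.065 | brain surface inside the scalp everywhere |
| corrugation | amplitude 5% of radius, frequency 6 | tilts ≥ 50% of normals > 5° off radial |
| source count | 2000 | ≈ 5 mm mean vertex separation |
| scalp offsets | 6.5 mm (OPM), 24 mm (SQUID-like) | point-magnetometer standoff |
| spacing grid | 85 → 15 mm in 5 mm steps | sweep range for the sensor packings |

The scalp must *not* be a sphere: on a sphere, radially sampled internal
and external harmonics become perfectly correlated and the separation
problem degenerates.  The cortical corrugation matters for the same kind
of reason — on an exact sphere with radial normals, every source would be
silent under the spherical conductor model.

Sensors are packed by area-weighted random seeding followed by Lloyd-style
short-range pairwise repulsion with exact star-shaped reprojection onto
the ellipsoid (points pushed below the helmet cut are clamped to the rim),
stopping when the largest move falls below 0.1 mm.  The packing is
deterministic for a given seed and reaches nearest-neighbour coefficients
of variation under 10%.  The sensor count at a spacing `d` follows the
hexagonal-packing law `N = area / (√3/2 · d²)` (~380 sensors at 15 mm on
the default scalp); a sensor count can also be requested directly.

Channel axes follow the tangential-swap rule: axis 1 is the outward
normal `[p, q, r]`, axis 2 is `normalize([−q, p, 0])` (orthogonal by
construction), axis 3 their cross product.  At an exact pole (p = q = 0)
the rule degenerates; the fallback projects the global x-axis onto the
tangent plane (giving `[1, 0, 0]` at the pole) and warns.

### Expansion origin

The origin is the least-squares sphere-fit centre of the scalp.  The
centroid of the sensor positions — a common alternative — sits high enough
on a helmet-style array that the deepest sources fall *outside* the
nearest-sensor radius, which breaks convergence of the internal expansion;
the sphere-fit centre keeps every source strictly inside every sensor
radius (distances 8–10 cm on the defaults) and is exposed as
`geometry.expansion_origin_for`.  The external-basis span is translation
invariant, so interference-side results do not depend on this choice.

## Forward model

Closed-form current dipole in a homogeneous conducting sphere (Sarvas).
The field depends on the sphere *centre* only, volume currents are implied
by the symmetry, and a radially oriented dipole is exactly silent — which
is why dipole moments follow the corrugated surface normals and why
columns with norm below 5% of the median are dropped before any variance
ratio is formed (> 99% of sources survive on the defaults).  Unit dipole
moments (1 A·m) and tesla outputs are used for logging; all downstream
metrics are scale invariant.

## Statistics and conventions

- Variance is the across-channel sample variance (mean subtracted, n − 1).
- Per-source attenuation is kept signed (≤ 0 dB); summaries report
  positive loss magnitudes, the worst case being the 2.5% quantile of the
  signed distribution with linear interpolation.  Sources with zero input
  variance are flagged undefined; variance ratios at the square of machine
  precision (< 1e-20) are flagged as fully removed (−∞ dB, +∞ loss).
- Adequacy thresholds are 99% variance explained in 95% of retained
  sources, for both the harmonic and the eigenvector family.  Eigenvector
  truncation is energy-ranked (descending eigenvalue).
- Shielding factors in dB convert with the amplitude convention
  `SF = 10^(dB/20)` (the SNIR model divides an interference *amplitude* by
  SF); attenuation factors convert from dB variance losses the same way.
  The radial white-noise advantage defaults to w = 2.5 with 1.5 as the
  documented sensitivity value.

## What the synthetic head does and does not show

The generator reproduces the features the analyses depend on: sensors at
varying distances from the origin, non-radial source orientations, a
scalp/cortex gap of realistic scale and approximately equidistant arrays.
Passing tests therefore demonstrate the geometric and statistical
machinery and the *direction and rough scale* of every effect: triaxial
arrays tolerate far higher interference orders than radial ones, on-scalp
sampling needs substantially higher neural model orders than offset
sampling (13 vs 7 here), and the eigenbasis is more compact than the
harmonic basis (137 vs 195 regressors at the densest sampling).

The synthetic cortex is a single superficial shell.  A real cortical mesh
additionally contains deep sources — sulcal walls and medial surfaces —
whose smooth, low-order lead fields overlap the external span almost
completely and pass the variance criterion with few regressors.  Their
absence shifts the medians: radial-array attenuation at order 3 is ~5 dB
here versus > 15 dB on a real head model, and the required eigenvector
count and saturation order land somewhat above the real-head values (137
vs < 100; 13 vs 11).  Conclusions that compare array designs are robust to
this; absolute per-source loss figures for a real head are not claimed.
Volume-current asymmetries, cross-talk, head movement and optimized
dual-axis orientations are likewise out of scope.

## Problem sizes

The default study scale — 2000 sources, ≤ ~380 sensors, orders ≤ 15 — was
chosen so that any single analysis runs in seconds and the complete
acceptance pipeline in well under a minute on one CPU, while keeping ≈ 5 mm
source spacing and the full 85–15 mm spacing sweep.  Unit tests run on a
12-sensor, 200-source bundle.
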