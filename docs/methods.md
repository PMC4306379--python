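# Methods

## Model and assumptions

A patch `s(D)` is the graph of `x3 = a3*sqrt(1 - (x1/a1)^2 - (x2/a2)^2)` over
the planar domain `D` of the upper half-ellipsoid, `a1 >= a2 >= a3 > 0`.
Surface uniformity means `P(s(X) in s(A)) = area(s(A))/area(s(D))` for every
measurable `A ⊂ D`; since the graph map is continuously differentiable this is
equivalent to `X` having planar density proportional to the area element
`sqrt(1 + (∂x3/∂x1)^2 + (∂x3/∂x2)^2)`, which works out to

```
f(x) = κ sqrt( (1 - δ1 u - δ2 v) / (1 - u - v) ),   u=(x1/a1)^2, v=(x2/a2)^2,
```

with shape parameters `δ1 = 1-(a3/a1)^2`, `δ2 = 1-(a3/a2)^2` satisfying
`1 > δ1 ≥ δ2 ≥ 0`, and `κ` the reciprocal patch area.  The change of variables
`y1 = x1/a1`, `y2 = x2/(a2 sqrt(1-y1^2))` maps `D` onto the rectangle
`D_g = (β2/a1, β1/a1) × (α2, α1)`; the transformed density is

```
f_g(y) = κ a1 a2 sqrt( (1-δ1 y1^2)(1 - m(y1) y2^2) / (1-y2^2) ),
m(y1) = δ2 (1-y1^2)/(1-δ1 y1^2).
```

When `δ2 = 0` (sphere, ellipsoid of revolution) the coordinates are
independent and the inverse-transform method applies marginal by marginal.
Patches are restricted to the upper half-ellipsoid; lower-half patches are a
reflection and are deliberately not modeled.

## Samplers

* **Sphere.** `y1` uniform on its interval; `y2 = sin(U·arcsin α1 +
  (1-U)·arcsin α2)`.  Exact.
* **Ellipsoid of revolution.** `Z = sqrt(δ1)·Y1` follows the semicircular law
  (density `∝ sqrt(1-z^2)`) restricted to `(r2, r1)`, `r_i = sqrt(δ1)β_i/a1`.
  Its CDF is the antiderivative `φ(t;1)`; `Z` is drawn by evaluating a
  tabulated inverse `φ^{-1}(·;1)` at a uniform point of `(φ(r2;1), φ(r1;1))`.
  The table holds `φ` at Chebyshev–Lobatto abscissae of `[-1, 1]` (default
  200 knots — they cluster where `φ'` vanishes and the inverse steepens) and
  is inverted with shape-preserving monotone cubic Hermite interpolation
  (PCHIP), so the interpolant cannot overshoot the monotone data.  The
  measured residual `max_u |φ(interp(u);1) - u|` is ~1e-7 at 200 knots and
  decreases with table size; the suite enforces `≤ 1e-6`.
* **Acceptance-rejection** (revolution `y1` marginal, for comparison):
  uniform proposals on `(β2/a1, β1/a1)`, envelope constant
  `c = ((β1-β2)/a1)·f*` with `f*` the marginal-density maximum — at 0 when
  the interval contains 0, else at the endpoint of larger density.  The
  acceptance probability is exactly `1/c`.  Proposals are drawn in chunks
  sized `1.2·c·(remaining)`; the loop runs until exactly `n` acceptances and
  records the proposal count up to the n-th acceptance, so the empirical rate
  is an unbiased estimate of `1/c`.  A spherical spec is rejected with a
  branch error: its marginal is uniform and AR degenerates to `c = 1`.
* **Metropolis–Hastings** (any shape; the only route for triaxial patches,
  whose marginals involve elliptic integrals): random walk on `D_g` with
  per-dimension Gaussian steps of 0.25× the domain widths, start at the
  rectangle center, burn-in 2000, thin 1 — all overridable through
  `HastingsConfig`, including an optional uniform independence proposal.
  Proposals outside `D_g` get zero target density and are rejected, which
  preserves the stationary law.  Acceptance uses the standard ratio
  `min(1, π(x')q(x|x')/(π(x)q(x'|x)))`; both supported proposals are
  symmetric in the relevant sense so the ratio reduces to the density ratio,
  computed on unnormalized log densities (no area normalization is ever
  needed for sampling).

Randomness: one `numpy.random.default_rng(seed)` stream per batch;
inverse-transform batches draw the full `U1` vector, then the full `U2`
vector, so a fixed seed reproduces batches bit-for-bit across platforms.

## Numerical choices

* **Patch area** is the integral of unnormalized `f_g` over `D_g`.  The
  integrable `1/sqrt(1-y2^2)` endpoint singularity is removed exactly by
  `y2 = sin θ`, leaving a smooth integrand handled by adaptive 2-D quadrature
  (`epsrel 1e-10`); the hemisphere and octant values agree with `2π` and
  `π/2` to rounding, and the revolution case matches the classical spheroid
  closed form to better than 1e-6 relative.
* **Equal-area chi-square binning**: grid edges at quantiles of the two
  marginal area profiles (`φ` in `y1`, `arcsin` in `y2`) — exact equal-area
  cells whenever `δ2 = 0`; each cell's true area is then recomputed by
  quadrature, so expected counts are correct even for triaxial patches where
  the grid is only approximately equal-area.
* **Normalization `κ`** is computed lazily: only when a caller asks for a
  normalized density.  All samplers work on ratios.
* **Domain handling**: `D` is treated as open; points within 1e-12 of the
  boundary are clamped onto it.  Shape classification (`is_sphere`,
  `is_revolution`) uses a relative semiaxis tolerance of 1e-12; a revolution
  spec below that tolerance must use the sphere branch, avoiding the 0/0 in
  `Z = sqrt(δ1)·Y1`.
* **Degree-4 octant**: the inverse stereographic projection from the south
  pole pulls the octant back to the quarter disc; a rational quadratic
  triangular patch maps the domain triangle onto that quarter disc (circular
  edge weight `sqrt(2)/2`); composing the two on homogeneous Bernstein
  coefficients with exact product formulas yields the degree-4 rational
  patch.  Every evaluated point lies on the sphere identically, so the
  on-quadric residual is rounding noise (~1e-16, bounded in tests at 1e-9).
  Ellipsoid octants scale the control points anisotropically, weights
  unchanged.  The rational de Casteljau recursion recomputes weights at every
  level (no pre-homogenization); the Bernstein form is the independent second
  route, and the two agree to ~1e-15 on random rational nets.
* **Trilinear interpolation** delegates to `scipy.ndimage.map_coordinates`
  with `order=1`, which is exactly the 8-corner blend; tests pin it to the
  closed-form corner blend, node interpolation, and exactness on affine
  fields.  Voxel convention: 0-based indices, `world = origin +
  index*spacing` at voxel centers, no extrapolation beyond the outermost
  centers; volumes are axis-aligned.
* **Fitting** is algebraic linear least squares: the sphere via
  `|p|^2 = 2c·p + (r^2-|c|^2)`; the ellipsoid of revolution, with a
  caller-supplied symmetry axis (default z), via
  `u^2 + ρ|v|^2 + b u + c·v + d = 0` in axis/transverse coordinates, from
  which center and semiaxes are read back.  Exact data is recovered to
  rounding; rank-deficient configurations raise.  General 9-parameter
  ellipsoid fitting is out of scope.

## Statistical testing choices

Distributional checks use p > 0.001 with seeds fixed in the suite, sized so
that correct samplers pass with wide margins (observed p-values 0.1–0.99).
KS and chi-square assume independent draws, which Markov chains do not
deliver at thin 1: a random walk with step 0.25× the width needs on the
order of a few tens of steps to decorrelate (roughly `(width/step)^2` over
the acceptance rate).  Chain output feeding such tests is therefore thinned
by 80 — comfortably above that scale — which is a property of the test
design, not of the sampler; the chain itself is valid at any thinning.

Problem sizes: chi-square uniformity at n = 50,000 over 50–100 bins;
KS at n = 50,000 (one-sample) and 20,000 per side (two-sample); the
chi-square-mean check averages 200 runs of n = 10,000; acceptance-rejection
efficiency uses ≥ 1e5 proposals; the phantom pipeline textures 50,000 points
from a 128³ voxel volume.

## What the phantom does and does not emulate

The phantom provides geometry and contrast, not MRI physics: a homogeneous
bright shell (radii `head_radius ± shell_thickness/2`) for the tendon
footprint, a dimmer spherical cap of known angular radius for the partial
tear, additive Gaussian noise.  Region membership is decided at voxel
centers and is set-exclusive before noise.  Intensities (background 20,
shell 200, tear 60, σ = 5) are separated far beyond the noise scale so the
tear-fraction check needs no tuned threshold; the ±2% tolerance of that
check absorbs the one-voxel blur band at the cap boundary
(perimeter·voxel/patch-area ≈ 2%).  Passing it shows the sampling → fitting
→ trilinear-texturing chain is metrically consistent; it says nothing about
bias fields, Rician noise, partial-volume effects or real tendon anatomy.

## Known limitations

* Inverse-transform sampling for triaxial patches is intentionally absent
  (elliptic integrals); Hastings covers that case.
* Benchmark timings are machine facts: the harness reproduces the
  methods-by-sizes table shape and reports medians (default 7 repeats after
  one warm-up), asserting nothing about values.
* The Hastings equilibrium ("burn-in sufficient") is a fixed-length choice,
  not a convergence diagnostic; the uniformity tests are the effective check.
* DICOM/NIfTI ingest is not implemented; volumes use the raw+header native
  format (any reader can be converted through `VoxelVolume`).
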