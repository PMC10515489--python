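# Methods

This note documents the measurement conventions, model assumptions,
numerical choices and known limitations behind `mpvol`.

## 2D morphometry

Particles are segmented from grayscale photographs by thresholding
(Otsu by default; a fixed gray value or pre-binarized input are
accepted), 8-connected labeling, and removal of components below a
minimum area (default 20 px, which suppresses thresholding specks).
Holes inside a component are retained as holes: they subtract from the
area but do not contribute to the perimeter, so the correction factor
remains driven by *outline* irregularity. All outputs are converted to
mm using the supplied pixels-per-mm scale (typical imaging setups run
18.5–19.2 px/mm for large frames and 42–44 px/mm for close-ups).

**Perimeter estimator.** The outline perimeter is the length of the
sub-pixel outer boundary polygon (marching squares at the 0.5 level of
the hole-filled mask) after smoothing with a circular moving average
whose window adapts to the contour size (≈ one eightieth of the vertex
count, odd, clipped to [3, 13]). Raw digital boundary lengths are
biased: a chain-code polygon overestimates a digital disk's perimeter
by ~5 %, which alone would depress circularity to ~0.90 for an ideal
disk and leak a spurious ~15 % into the cubed correction factor.
Corner-weight corrections (e.g. 0.948/1.340) fix smooth shapes but
misestimate polygonal ones. The adaptive smoothed-contour estimator
keeps both regimes within 2 %: disk circularity 0.98–1.00 across radii
20–200 px and square circularity within 2 % of π/4. The same single
estimator feeds circularity and the correction factor everywhere; the
raw contour length is available via `outer_perimeter(..., smooth_window=1)`.

**Best-fit ellipse.** Second-central-moment fit; full axis length =
4·√(covariance eigenvalue). This is the ImageJ convention, so *M* and
*m* are full diameters and the ellipsoid volume is (π/6)·*M·m·H*. The
area-preserving rescaling variant used by some ImageJ builds is not
applied; measured area and π/4·*M·m* generally differ by < 2 % for
convex particles.

**Feret diameter.** Maximum pairwise distance between convex-hull
vertices of the same sub-pixel boundary polygon. Degenerate masks
(single pixels, 1-px lines) yield flagged results rather than errors.

**Fibers.** Length is the geodesic length of the longest path through
the morphological skeleton (Dijkstra double sweep on the 8-connected,
√2-weighted skeleton graph), smoothed with a small moving average to
remove chain-code bias on curved centerlines, and extended at each tip
by the local half-width (the skeleton stops short of the fiber ends by
about one half-width). Width is twice the mean Euclidean
distance-transform value along the path. A particle qualifies as a
fiber when skeleton length ≥ 5 × width; for CLI routing the moment
aspect-ratio threshold (≥ 5) is used instead, since routing happens
before the skeleton is computed. Branched skeletons are measured along
the longest path and logged.

**Circularity** 4π·*A*/*P*² is capped at 1: rasterization noise can
push small near-circular particles slightly above the theoretical
bound. Observed beach-particle circularities span roughly 0.05–1.

## Volume models

Conventions and defaults:

* `K_c = 0.1` (cube model), `K_I = 0.4` (cylinder model), fiber void
  fraction 0.40 — the values calibrated in the originating studies.
* Particle "length" *L* is the best-fit-ellipse major axis.
* Ramanujan's **first** approximation is used for the ellipse
  perimeter, as in the model's definition. Its relative error against
  numerical arc-length quadrature is < 1e-5 at aspect ratio 2, ≈ 2e-4
  at 5 and ≈ 1.2e-3 at 13; this is far below the correction factor's
  sensitivity to real outline noise, but it is *not* below 1e-4 over
  the whole observed aspect-ratio range — the second approximation
  would be, at the cost of departing from the model as published.
* The correction factor is **not** clamped at 1 by default: values
  slightly above 1 expose perimeter-estimator bias instead of hiding
  it (a clamp flag exists; values above 1.05 are logged as suspicious).
* The Tanoiri height rule is a per-group affine function of a chosen
  axis. The originating calibration coefficients for the "fragments"
  and "PE/PP pellets" groups are not publicly tabulated, so the
  shipped groups are explicit placeholders that warn on every use.
* The fixed-width fiber model variant aimed at ~15 μm fibers is
  excluded as out of the size range handled here.

## Evaluation against measured volumes

A *throw* is one deposition + imaging of a mixture; batches are
replicate subsamples; groups are shape/size categories. The ratio
V_modeled/V_measured is aggregated as: batch value = mean over its
throws; group mean and sample SD (n−1 throughout) over batch values —
not over pooled throws. Per-batch relative SD over throws is reported
alongside.

**F-test.** Two models are compared per batch through the ratio of
their residual sums of squares over throws, residual = modeled −
measured collective volume (per-particle residuals are impossible
because only collective volumes are measured). The larger RSS goes in
the numerator and the orientation is recorded; the two-sided p-value
uses the F distribution with (n_throws, n_throws) degrees of freedom —
the residuals are errors about zero, not deviations from a fitted
mean, so no degree of freedom is spent. Normality is assumed, not
tested; decisions are reported at α = 0.05 and 0.1. Single-throw
batches (fibers) are skipped with a warning.

**Recalibration.** For each throw, the scalar free parameter (K_c,
K_I, or the Tanoiri height slope) minimizing the squared *relative*
error of the collective volume is found by bounded scalar search in
[0, 1] (slope: [0, 2]). Relative error makes small and large mixtures
weigh equally. The collective volume is strictly increasing in each of
these parameters, so the optimum is unique. Only the Tanoiri slope is
optimized — fitting both affine coefficients against a single scalar
per throw is underdetermined (any point on a line of (slope,
intercept) pairs reproduces the measured volume exactly). The
corrected-ellipsoid model has no calibration parameter and is
rejected explicitly, as are the Simon and Medina models.

## Displacement volumetry and QA

For mixtures too large for a pycnometer, volume comes from flask
weighings: V = (W_MP + W1 − W2)/ρ, with ρ = 0.81 g/cm³ for 96 %
ethanol and a 25.0 mL nominal flask volume. Units are g and cm³ at
the interface (mm³ internally, ×1000). Negative computed volumes are
flagged invalid, never clamped — they indicate a weighing error.
QA checks: relative SD of replicate flask weighings, and the min–max
spread of a reference object's imaged area across a throw series
(pass < 1 %).

## Synthetic particles

The simulator is the ground-truth engine: it produces star-shaped
solids R(u) = r_ellipsoid(u)·(1 + amplitude·f(u)), where f is a
zero-mean, unit-variance, band-limited spherical-harmonic field
(degrees 2 to ≈ π/angular_scale, default scale 0.3 rad → degree ~10,
clipped at 3σ). The band-limited radial field emulates the
micro-valley/crack roughness that motivates the correction factor;
amplitude is a fraction of the local radius and must be < 1 (larger
values risk self-intersection).

* **Volume oracles.** The reference volume is the divergence-theorem
  sum over a triangulated surface whose vertices sample the same
  bilinear radius table (icosphere, 10 242 vertices for single
  particles; 2 562 for bulk mixtures). An independent voxel-counting
  oracle (pitch c/20, capped at ~4e6 voxels) agrees within 1 %.
* **Projection.** The lowest-energy resting pose is operationalized as
  principal-axis alignment: the direction of smallest principal-axis
  extent goes vertical (true contact mechanics is out of scope). The
  silhouette is rasterized at 40 px/mm by slicing the inside test over
  33 vertical levels. Repeat throws re-project with a random in-plane
  spin and an optional flip; for near-resting particles this
  reproduces the observed small (< 3 %) throw-to-throw variation.
* **Mixtures.** Defaults emulate a sieved 2–5 mm secondary-MP group:
  250 particles, major axes uniform over the sieve range, aspect
  ratios uniform in 1–3 (observed ratios across all groups reach 13),
  heights following the Simon-consistent rule c = b²/a so that model
  error isolates surface roughness. All randomness flows from one
  seeded generator; per-particle seeds are recorded in the truth
  table.

What the simulator does *not* reproduce: lighting/shadow artifacts,
touching or overlapping particles, translucent material, weathered
concavities beyond a radial field (true cracks are non-star-shaped),
and the sub-pixel blur of real optics. Passing the simulation tests
therefore shows the geometric chain is right, not that segmentation of
difficult real photographs is solved. Roughness levels are choices,
not fits: no quantitative roughness characterization of real beach
particles is available.

## Problem sizes and tolerances

Directional simulation checks use seeded 250-particle mixtures at
40 px/mm (the size of one real throw); oracle checks use single
particles at the resolutions above. Recalibration recovery uses 30
throws of 20 particles with 5 % lognormal measurement noise. Exact
identities (the C_f decomposition, displacement round-trip) are
asserted to machine precision; raster-dependent quantities carry 1–3 %
tolerances consistent with the discretizations involved.

## Known limitations

* The perimeter estimator, though validated on disks, squares and
  ellipses, has no universal guarantee on pathological outlines;
  circularity of very small particles (< ~10 px across) is noisy.
* Tanoiri coefficients ship as placeholders and must be supplied from
  a calibration before quantitative use.
* The F-test degrees-of-freedom convention is a documented choice;
  with three throws per batch the test has little power either way.
* Mass conversion (density tables) and surface-area models are out of
  scope.
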