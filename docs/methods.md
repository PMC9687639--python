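# Methods

## Problem and scope

Biomechanical metrics of abdominal aortic aneurysms (AAA) — peak wall
stress (PWS) and mean wall stress (MWS) computed from nodal von Mises
stress on a reconstructed wall surface — are highly sensitive to the region
they are computed over. Including non-dilated neck or branch segments
dilutes MWS and blurs group contrasts. `sacisolate` implements an
objective, repeatable delimitation of the dilated sac from the wall
geometry alone, plus the stress metrics and statistical comparisons that
delimitation enables.

The package deliberately contains **no finite-element solver**: it consumes
a triangulated wall surface and a per-node scalar stress field produced
elsewhere, and for development and validation it generates synthetic
geometry and Laplace-law stress surrogates (below).

## Sac-isolation algorithm

Given a wall surface with the craniocaudal direction along Z (supine CT
convention; superior = larger Z):

1. **Centre** the node cloud at the origin (unweighted node centroid; a
   deliberate choice over area-weighted centroids — it is exactly
   reproducible and independent of triangulation density conventions).
2. **Rotate** the nodes about Z by increments of θ_z degrees,
   N = 360/θ_z projections in total. θ_z must divide 360; the supported
   sweep is 0.5°–90°.
3. **Project**: after each rotation drop the depth (y) coordinate, bin z
   into `z_bins` uniform bins (default 100) over the z-extent and take, per
   non-empty bin, the extreme x on each side of the dividing axis x = 0:
   the right branch is the per-bin maximum, the left branch the minimum.
   Empty bins are skipped, never interpolated. Working on the node cloud
   (not the triangle silhouette) keeps the operation exact and cheap;
   convex hulls were rejected because they erase the neck concavity.
4. **Fit** each branch with a trigonometric Fourier series
   x(z) = a₀ + Σᵢ aᵢ cos(i w z) + bᵢ sin(i w z), i = 1..n, default n = 7
   (1–8 supported for the residual study). The fundamental frequency w is
   a *fitted* nonlinear parameter.
5. **Detect** the sac limits from the analytic second derivative x''(z)
   of the fitted series on a ≥500-point grid: the bulge apex is the z of
   maximum |x|; the inferior/superior limits are the nearest local extrema
   of x'' *of opposite curvature sign to the apex* below and above it —
   the flanks where curvature flips from bulge-type to neck-type. Extrema
   of the right type but the same curvature sign (ripples on the apex
   plateau of an oscillatory fit) are not accepted as limits. A
   `zero_crossings` mode (true inflection points of x) is available behind
   the `mode` switch for sensitivity analyses.
6. **Aggregate**: each rotation contributes two branch detections; the
   final bounds are the medians of the per-branch inferior and superior
   limits, excluding branches whose detection fell back to a mesh end
   (fallback-flagged). The median was chosen over the mean for robustness
   to occasional wild fits. The sac node mask is all nodes with z between
   the bounds (in the centred frame), so the result is invariant to
   translation and to node reordering.

Degenerate inputs fail loudly rather than silently returning the whole
mesh: a straight tube (|x''| < 1e-9 everywhere) raises "no sac detected",
and isolation aborts if more than half of the branches raise errors.

### Fourier-fit numerics

* Initialisation: w₀ = 2π/(z_max − z_min); harmonic coefficients from a
  linear least-squares solve at fixed w.
* Solver: trust-region reflective least squares with analytic Jacobian;
  w bounded to [w₀/50, 50 w₀].
* Restarts: initial frequencies {1, 0.5, 2}·w₀ (plus a zero-padded warm
  start from the previous fit during the 1→8 harmonic sweep, which makes
  the sweep's RMSE provably non-increasing). A converged candidate with
  RMSE ≤ 2% of the branch amplitude is accepted immediately: silhouette
  branches carry binning/discretization error of that order, and further
  restarts would only chase noise. If no candidate converges, a typed fit
  error carries the best RMSE reached.
* The whole pipeline is deterministic: identical inputs give bit-identical
  masks.

## Stress metrics

* **PWS** = 99th percentile of masked nodal stress, linear interpolation
  between closest order statistics (inclusive). The convention is stated
  because percentile definitions differ across tools and the metric must
  be bit-reproducible.
* **MWS** = unweighted mean of masked nodal stress after removing nodes
  within `exclude_boundary_rings` topological rings of any open mesh edge.
  Defaults: 1 ring for the entire aneurysm (shell-model boundary conditions
  inflate stress at clipped ends), 0 for the sac (its limits are
  algorithmic, not mesh edges). Node-wise averaging (not area-weighted) is
  used; it matches the standard reporting convention but does tie MWS to
  mesh density, a known limitation.
* Region comparison (sac vs entire, same cases) uses a paired t-test;
  group comparison (stable vs unstable) a two-sided Mann–Whitney U with
  tie correction, exact for small tie-free samples. All tests are
  two-sided and uncorrected for multiplicity.

## Constitutive models

The anisotropic wall model is a six-term exponential strain-energy
function of the in-plane Green strains (circumferential E_θθ,
longitudinal E_LL, shear E_θL):

W = b₀·(e^{½b₁E_θθ²} + e^{½b₂E_LL²} + e^{b₃E_θθE_LL} + e^{½b₄E_θL²}
  + e^{b₅E_θθE_θL} + e^{b₆E_LLE_θL} − 6),

with defaults b₀ = 0.14 kPa, b₁ = 477.0, b₂ = 416.4, b₃ = 408.3 and the
shear/shear-normal couplings b₄ = b₅ = b₆ = 0 (they are not required to
fit experimental biaxial data; they are overridable). b₀ carries the
stress units; b₁..b₆ are treated as dimensionless exponent multipliers —
the only dimensionally consistent reading of the form. W = 0 exactly at
zero strain; |E| < 1 is enforced as a sanity bound; an overflowing
exponential raises a typed error naming the term.

The intraluminal thrombus (ILT) uses the standard two-parameter isotropic
polynomial W = c₁(I₁−3) + c₂(I₂−3) with defaults c₁ = c₂ = 2.6 N/cm².
The functional form is the package's design choice from the experimental
ILT modelling literature; only the two parameter values are inputs.

These evaluators document the constitutive content and serve users with
their own strain data; they are *not* used to solve equilibrium.

## Synthetic stress surrogate

`synthetic_stress_field` produces a thin-walled-tube (Laplace) von Mises
surrogate: per node, the local radius r(z) is the distance from the Z axis
averaged over a 2 mm z-window, and σ = P·r/t, converted with
1 mmHg = 133.322 Pa = 0.0133322 N/cm², plus optional Gaussian noise
(clipped at zero), deterministic per seed. Defaults are the reference
loading of image-based AAA stress analysis: P = 120 mmHg systolic,
t = 1.9 mm uniform wall thickness. For a 10 mm-radius tube this gives
1.599864·10/1.9 ≈ 8.42 N/cm².

What the surrogate reproduces: the first-order dependence of wall stress
on local dilatation (stress increases with radius, maximal at the maximum
diameter). What it does not: stress concentrations from curvature and
asymmetry, ILT load sharing, bending near necks, residual stress, material
heterogeneity. Tests that pass on the surrogate therefore validate the
*isolation and metric machinery*, not FEA fidelity on real anatomies.

## Synthetic geometry

A fusiform sac is a surface of revolution (optionally laterally offset)
about Z: r(z) = r_neck + (r_max − r_neck)·bump(2z/L_sac), where `bump` is
a raised cosine multiplied by a quintic smoothstep window over the
outermost 20% (`edge_smoothing = 0.2`) of the sac half-length. The family
was chosen so that radius, slope and curvature all vanish continuously
(C²) at the ground-truth bounds z = ±L_sac/2, placing the analytic
curvature-change flank just inside the bound — detectable, with a small
known inward bias. Asymmetry shifts the cross-section centre by
`asymmetry·(r_max − r_neck)·bump`, mimicking anteriorly bulging sacs.
Tubes are open-ended, mirroring clipped clinical reconstructions, which
also exercises the open-edge ring exclusion in MWS.

Default base geometry: neck radius 10 mm (2 cm non-dilated aorta), max
radius 25 mm (≈5 cm sac, the clinical repair threshold), sac length
60 mm, necks 25 mm per side; resolution 100 axial × 64 circumferential
nodes (cohort simulations use 48 × 24 — the desk-scale trade of mesh
density for case count).

### Cohort simulation and its calibration

`make_cohort` draws per-case geometry by multiplying the four base
parameters by clipped Gaussian factors. The relative sds are
`geometry_jitter` (default 0.15) scaled per parameter: ×2.0 for neck
radius, ×0.8 for max radius, ×1.0 for the lengths. The weighting reflects
clinical ranges: non-dilated infrarenal diameters span roughly 15–30 mm
(large relative spread), while sacs reaching analysis are concentrated
near the repair threshold (smaller relative spread). With the Laplace
surrogate this yields between-case sac-MWS sd ≈ 1.6 N/cm² and
entire-aneurysm MWS sd ≈ 1.7 N/cm².

Unstable cases add a constant `unstable_stress_offset` (default 3 N/cm²)
to every node inside the ground-truth sac only. An a-priori power sketch
for 20 vs 20 cases: the sac metric sees the full offset
(d ≈ 3/1.6 ≈ 1.9, rank-sum power ≈ 99%), while the entire-aneurysm metric
sees it diluted by the sac's node fraction (≈0.55 of the z-extent,
d ≈ 1.65/1.7 ≈ 1.0, power ≈ 75–85%). The qualitative signature — the group
difference is detected reliably only under sac isolation — is therefore
built into the study design, and the simulations measure where the rates
actually land.

In the group-difference study the power arm runs real isolation at a 90°
increment (4 projections): the increment-equivalence property (bounds at
7.5° match 0.5° within one z-bin) justifies coarse increments on these
near-axisymmetric sacs, and 4 projections × 2 branches still aggregates 8
detections per case. The null-calibration arm (offset 0, 200 replicates)
uses the generator's ground-truth masks: under label exchangeability the
null distribution of the rank-sum p-value does not depend on how the mask
was obtained, so isolation there would only add compute.

## Known limitations

* The detected bounds sit systematically ~8–9% of the sac length inside
  the ground truth on the synthetic family: the 7-harmonic fit smooths the
  curvature transition and pulls its extremum toward the bulge. This bias
  is stable across seeds and increments; users comparing regions across
  cases inherit a consistent, slightly conservative sac.
* Tortuous aneurysms whose centreline leaves the Z axis violate the
  rotational-projection premise; the algorithm targets AAA segmented
  between renal arteries and bifurcation without iliac/visceral branches.
* MWS is node-density weighted by construction (unweighted node mean).
* The Laplace stress surrogate is a development harness, not a substitute
  for FEA on clinical data (see above).
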