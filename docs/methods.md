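# Methods

This package implements and compares four ways of turning a respiration-
correlated CT pair (maximum exhale, maximum inhale, and the deformable
registration linking them) into a voxelwise lung-function map, together
with the downstream functional-avoidance analysis chain: percentile
functional contours, Dice overlap against the density-change reference,
dose-function metrics (fMLD, fV20), simulated reader agreement, and
nonparametric paired statistics. Because no clinical 4DCT data ship with
the package, every analysis runs on synthetic breathing phantoms with
analytic ground truth.

## Conventions

Volumes are `(nx, ny, nz)` arrays in fixed (x, y, z) axis order; the world
coordinate of voxel center `i` is `origin + i * spacing` (mm). The
displacement field `u` lives on the exhale grid and points into inhale
space (`x ↦ x + u(x)`, pull/backward-warp semantics), treating exhale as
the planning reference. All volumes are read and written as NIfTI-1 with a
diagonal affine; displacement fields are 4-D with a final length-3 axis.

## The four function images

**Density-change ventilation (HU).** Under the two-material model a voxel
is a mix of air (−1000 HU, density 0) and water-like tissue (0 HU, density
1), so density is ρ = (HU + 1000)/1000. With H_ex the exhale HU and H_in
the inhale HU pulled to the exhale grid,

    SV(x) = 1000 (H_in − H_ex) / (H_ex (1000 + H_in)),

the fractional change of the voxel's *air* volume. Against a phantom with
Jacobian J and exhale density ρ it satisfies SV = (J − 1)/(1 − ρ); the
recovery tests compare against that analytic target rather than J − 1,
which would conflate the air-normalization factor with method error.
Voxels with H_ex ≥ −10 (no air signal) or H_in ≤ −990 (no tissue signal)
are undefined; more than 20 % excluded voxels indicates a mask/image
mismatch and raises.

**Subregional estimation.** The three uncertainty-controlled methods share
a two-stage design: measure a quantity over overlapping cubic lung
subregions (default window 8 voxels, stride 4; 50 % overlap keeps the
voxelwise problem determined), then recover a voxelwise image by
constrained linear least squares. Every subregional estimate carries a
standard error, and the tolerance parameter τ (default 0.01) bounds the
relative uncertainty of the Monte Carlo estimates.

* *Integrated Jacobian (IJF):* each subregion's deformed volume is the
  union of its voxel cells' images; cells are split into 5 tetrahedra
  whose vertices are mapped through the trilinearly interpolated field.
  The volume is estimated by hit-or-miss sampling in the mapped-vertex
  bounding box with N = ⌈1/(4τ²)⌉ points — the smallest N for which the
  binomial standard error is guaranteed ≤ τ·(box volume) for *any* hit
  fraction (worst case p = 1/2). Face ties count as hits (a measure-zero
  convention fixed for determinism); an exact tetrahedral-sum oracle backs
  the estimator in tests. Per-region seeds derive from the region's window
  corner, so results are invariant to region ordering.
* *Mass-conserving volume change (MCVC):* the subregional Jacobian is the
  ratio of the mean exhale density over the subregion to the mean inhale
  density at the points the field maps the subregion onto (exhale fixed as
  the reference side; the SE propagates both within-region sample
  variances through the ratio). A density floor of 0.01 guards the
  denominator.
* *Perfusion (mass-change magnitude):* per voxel, Δm(x) = J(x)·ρ_in(x+u(x))
  − ρ_ex(x), mass per unit exhale voxel volume; the subregional value is
  mean |Δm|. The Jacobian ingredient must be *deformation-derived* — by
  default a voxelwise reconstruction from exact tetrahedral deformed-volume
  ratios — because a density-ratio Jacobian algebraically cancels the very
  mass changes the method measures.

**Voxelwise reconstruction.** All three solve

    min_j  Σ_r w_r (mean_{i∈r} j_i − v_r)² + λ ‖D j‖²
    s.t.   j_i ≥ ε,  optionally  Σ_i vox·j_i = V_global

with w_r = 1/SE_r², capped at 100× the median weight and normalized to
mean 1 (uncapped weights from near-zero SEs let the solver interpolate
mutually inconsistent overlapping means and oscillate), and D the
first-difference operator over the lung adjacency. λ (default 10⁻³) fixes
the null space the overlapping means leave; it is checked not to bias
constant-field recovery and is switchable to 0. ε (default 0.05) is the
physical lower bound on the Jacobian; the perfusion image uses a plain
non-negativity bound. IJF adds the global equality that the recovered
total deformed volume equal the inhale lung-mask volume, imposed as a soft
row at the data-weight scale and then made exact by a multiplicative
rescale (clipped at ε; the residual violation is reported in the
diagnostics). The solver first tries the unconstrained sparse least-squares
path (LSMR); if the minimizer violates the bound it falls back to a
bound-constrained trust-region solve.

## Synthetic phantoms

The generator emulates the study conditions the imaging methods assume:

* an ellipsoidal lung (semi-axes 32 % of the grid extent) of smooth
  parenchyma-like density ~0.2 (≈ −800 HU, ±15 % sinusoidal texture)
  inside a larger soft-tissue body; the texture is continuous across the
  lung boundary so resampling paths see no artificial density jump;
* an analytic breathing transform — affine or separable low-order
  polynomial — whose Jacobian determinant J\* has a closed form; the
  default is a 5 %-per-axis expansion (J ≈ 1.16, a typical tidal volume
  change); transforms that fold (J\* ≤ 0 in the lung) are rejected;
* mass-consistent phases: the inhale volume is evaluated *analytically* on
  its own grid as ρ_in(y) = ρ_ex(T⁻¹ y)/J\*(T⁻¹ y) (fixed-point inversion
  of the displacement), so the pair conserves tissue mass up to
  discretization only (audited at ≤ 0.5 %);
* ventilation defects as local attenuation of the motion: displacement is
  scaled by 1 − a·b(r) with b = 1 in a spherical core and a C¹ cosine
  taper to 0 at the defect radius. With a = 1 the core does not move
  (J = 1 exactly); the taper shell slightly over-expands, as tissue
  surrounding a non-ventilating region must. The recorded defect mask is
  the core. Because the *transform* is modified, all four methods see one
  consistent physical scene;
* perfusion anomalies as implanted inter-phase mass changes m(x), added to
  the numerator of the inhale density so the per-voxel mass change equals
  m(x) exactly;
* Gaussian HU noise (default sd 20 HU, typical 4DCT reconstruction noise)
  added after the mass-consistent construction;
* conformal dose: prescription inside a spherical target with Gaussian
  radial falloff from the target surface;
* simulated binary reader calls with configurable sensitivity,
  specificity, and lobe-location error.

What the phantoms do *not* emulate: real anatomy (airways, vasculature,
lobar fissures), registration error (fields are analytic, not estimated),
CT artifacts beyond white noise, and genuine physiology behind reader
calls. Passing tests therefore demonstrate correctness of the estimators
and the analysis chain under known truth — not clinical accuracy.

## Downstream analysis

Function images on different scales are rank-transformed to percentile
images over the whole lung (mid-rank ties, 100·(rank − 0.5)/n), which is
invariant to any strictly increasing transform — so the HU method's SV and
the novel methods' J compare without rescaling. Functional contours are
the voxels at or above the 25/50/75 levels (inclusive, matching the
≥25 %/≥50 %/≥75 % convention); a constant image maps to all-50, making the
≥75 % contour empty rather than full (the conservative reading). Dice is
2|A∩B|/(|A|+|B|), defined as 1 when both contours are empty.

fMLD is the unweighted mean dose inside a functional contour; fV20 the
percentage of contour voxels receiving ≥ 20 Gy (inclusive). The default
per-patient table is 4 methods × 3 thresholds × 2 metrics = 24 records;
undefined entries (empty contour, missing method) are NaN-flagged rows,
not omissions.

Across patients, each (metric, threshold) cell is tested with a Friedman
test (within-patient mid-ranks, standard tie correction, χ² approximation
with k − 1 df), followed by post-hoc two-sided Wilcoxon signed-rank tests
of each novel method against the HU reference. Zero differences are
dropped (count logged). For n ≤ 25 pairs the exact null distribution over
all 2ⁿ sign assignments is computed by convolution over doubled mid-ranks
(ties handled); larger n uses the normal approximation with tie and
continuity corrections. The Bonferroni-adjusted alpha is the family alpha
over the number of comparisons *truncated* (not rounded) to three
decimals: 0.05/3 → 0.016. Reader agreement against the reference arm is a
confusion summary (sensitivity, precision, specificity, accuracy); in
location-aware mode a positive call with the wrong lobe counts against the
test arm as a false positive (the strict reading; the paired-lobe match is
exact since each simulated call carries one lobe). The regional
heterogeneity criterion compares mean function in the peritumoral shell
(lung within 30 mm of the tumor, tumor excluded) against the rest of the
lung and passes at a decrease of ≥ 15 % (inclusive boundary).

## Problem sizes and numerical choices

The analysis cohort is eight 32³ phantoms at 2 mm voxels; eight is the
smallest cohort for which the exact Wilcoxon can fall below the adjusted
alpha (2/2⁸ ≈ 0.008 < 0.016). Recovery accuracy is validated on 48³
noise-free phantoms (≈ 14 000 lung voxels, ≈ 340 subregions), where the
integrated-Jacobian and mass-conserving maps recover the analytic Jacobian
with voxelwise RMSE well under 2 % and the density-change map recovers its
analytic target under 3 %. Estimator/oracle agreement uses 100 random
affine subregions at τ = 0.001 and 1000-case brute-force checks for Dice
and confusion counting; type-I-error calibration uses 5000 simulated null
families of 20 pairs. LSMR and the bounded trust-region solver run at
tolerance 10⁻¹⁰; regional SEs are floored at max(10⁻⁶, 10⁻⁴·median value)
before weighting.

## Known limitations

* The voxelwise reconstructions smooth across the λ penalty; very sharp
  function boundaries are recovered with a ~1-window transition band.
* The hit-or-miss N uses the worst-case binomial bound, which oversamples
  subregions whose mapped tets fill their bounding box (hit fraction near
  1); adaptive/stratified sampling is out of scope.
* The location-aware reader agreement supports one lobe per call;
  multi-lobe defects are not modeled.
* Whole-lung percentile ranking is implemented; per-lung ranking is not.
* The phantoms use a single uniform lung mask; exclusion of airways and
  vasculature is the caller's responsibility via the supplied mask.
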