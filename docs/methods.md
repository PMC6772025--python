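# Methods

This note documents the models, numerics, and design choices behind
`cortrad`, and what the synthetic tests do and do not establish about real
data.

## Diffusion model and tensor estimation

Signals follow the single-tensor model S = S₀ exp(−b gᵀDg). The fit is
ordinary log-linear least squares over all volumes for the 7 unknowns
(ln S₀ plus the 6 independent tensor components, stored in the fixed order
Dxx, Dxy, Dxz, Dyy, Dyz, Dzz). This estimator is deterministic and exact on
noiseless single-tensor data, which is what the phantom round-trip tests
rely on; a weighted or robust fit is out of scope. Non-positive signals are
floored at `clamp_eps · S₀` (default 10⁻⁶) before the log and the voxel is
flagged (QC bit 1); fitted tensors that are not positive definite are
retained but flagged (bit 2) rather than repaired, and flagged voxels are
excluded from ROI averages. Eigenvalues are sorted descending; eigenvector
signs follow a fixed first-nonzero-component-non-negative convention, which
is immaterial downstream because every radiality metric is antipodally
invariant (tested bit-exactly). Voxels with λ₁ ≈ λ₂ (relative gap ≤ 10⁻⁶)
have no defined principal direction and are flagged (bit 4). FA uses the
standard normalized eigenvalue-dispersion form with FA(0) ≡ 0.

The default acquisition scheme mirrors a high-b postmortem protocol: 54
directions at b = 4500 s/mm² on a golden-spiral (near-isotropic) lattice
plus six b = 0 volumes. Rician noise is applied on the magnitude signal as
√((S+n₁)² + n₂²) with per-channel Gaussian sd S₀/SNR, the magnitude-MRI
convention.

## Radial geometry

The radial direction across the ribbon is defined via a harmonic potential:
Laplace's equation on cortex voxels with Dirichlet data 0 at the
white-matter surface and 1 at the pial surface, insulating (Neumann)
behaviour toward `outside` voxels, 6-connected stencil. This is the
standard curvature-respecting realization of "lines within the cortex in a
radial direction"; the original implementation it stands in for is
proprietary, so only agreement with analytic geometry is claimed, never
equivalence with any particular software.

**Embedded boundary.** Binary tissue labels localize the true boundary only
to about half a voxel. The solver therefore imposes each Dirichlet value at
a sub-voxel crossing: along each grid axis, the boundary is placed where
the Gaussian-smoothed (σ = 1 voxel) indicator of the boundary tissue
crosses 0.5, and a boundary neighbor at fractional distance h contributes
with weight 1/h (Shortley–Weller). Crossings are clamped to [0.25, 1]
voxels. On a flat slab this recovers the voxel-center solution φ = z/T to
machine precision; on a 1 mm spherical annulus (a = 20 mm, b = 40 mm) the
potential matches (1/a − 1/r)/(1/a − 1/b) to < 10⁻² max error and the field
direction matches the outward radius to < 2°, both evaluated over the
cortex interior with the two-voxel boundary shell excluded — inside that
shell, label quantization (the partial-volume zone that ROI protocols
deliberately avoid) dominates and errors up to ~0.02 / ~8° remain
irreducible from binary labels.

**Solver.** The system is symmetric positive definite; the default path
assembles it sparsely and solves by conjugate gradients, then verifies the
stopping contract — the largest red-black Gauss–Seidel update below `tol`
(default 10⁻⁶) — with a final sweep. `method="gauss-seidel"` iterates the
sweeps directly (default cap 10⁴); CG was adopted because plain sweeps need
O((T/h)²) iterations and become the dominant cost on thick ribbons. Cortex
components not in contact with both boundaries cannot carry a meaningful
potential; they are excluded from the solve, set to NaN, and flagged
downstream.

**Field and profiles.** The radial field is the potential gradient from
non-uniform central differences (boundary samples at their sub-voxel
crossings), normalized to unit length and oriented toward increasing
potential; voxels with gradient norm < 10⁻⁸ — all of them, for a constant
potential — are flagged. Profiles are traced from every unflagged
white-matter-adjacent cortex voxel by fixed-step Euler integration
(default step 0.25 mm, trilinear field interpolation), starting half a
voxel behind the seed center (the white-matter face) and stopping on
leaving the cortex (the crossing endpoint is kept), on non-increasing
potential, or at 3× the nominal thickness (median of 1/|∇φ|). On the slab,
arc lengths equal the thickness to within one step; on curved geometry the
staircase quantization of seed and exit surfaces adds up to about one voxel
of scatter. Profiles live in continuous voxel coordinates; the affine is
applied only at export.

## Radiality metrics and aggregation

Per voxel: θ_R = arccos |e₁ · r|, ParlPD = λ₁ cos θ_R, PerpPD = λ₁ sin θ_R,
so ParlPD² + PerpPD² = λ₁² holds identically. Angles are reported in
radians; diffusivities in 10⁻³ mm²/s at every reporting interface. The
scalar θ_R is averaged arithmetically along each profile (nearest-voxel
sampling by default; trilinear available) — not via dyadic/vector averaging
— because the profile-averaged scalar is the defined quantity. Profile
means are averaged, unweighted, over the profiles seeded inside the ROI
mask, excluding the single first and last slice of the ROI's slice range
(the most literal reading of the terminal-slice exclusion); whether the
original analysis weighted by arc length is unstated, so the unweighted
mean is the documented choice. Voxels flagged at any earlier stage (QC,
PDD-degenerate, radial-flagged, λ₁ < 0) never enter the averages.

## Synthetic phantoms and cohorts

The phantom emulates what the analysis assumes: a cortical ribbon bounded
by white matter and pial CSF whose dominant diffusion axis is radial up to
axially symmetric scatter. Orientation scatter uses a Watson-type axial
distribution about the local radial axis with concentration κ, sampled by
rejection on cos θ (density ∝ exp(κ cos²θ)); κ = ∞ gives perfect
radiality, κ = 0 uniformly random axes, where the mean per-voxel angle has
the closed form ∫₀¹ arccos(c) dc = 1 rad. An optional tangential layer at a
fractional-depth interval re-aims the mean axis perpendicular to radial,
emulating the heavily myelinated tangential band at mid-depth of primary
visual cortex. Defaults: 48³ grid at 1 mm isotropic (the acquisition's
0.94 mm rounded to the desk scale), eigenvalues (0.8, 0.2, 0.2) × 10⁻³
mm²/s (prolate, in the reduced-diffusivity regime of fixed tissue). The
default ribbon is 10 mm thick — several times real cortex — so that slab
ROIs contain ≥ 10⁴ voxels for tight Monte-Carlo comparisons; geometry
tests that probe discretization use the annulus instead. No quantitative
tissue dispersion values are available to calibrate κ against disease, so
phantom κ ranges are free parameters.

Cohorts draw per-subject κ from group-specific normals (defaults: case
2.0 ± 0.8, control 6.0 ± 1.2 — cases more dispersed, hence larger AngleR),
plus per-subject eigenvalue variability (lognormal overall scale sd 0.10,
anisotropy factor sd 0.15) so that MD and FA vary biologically across
subjects. Each scalar histology measure is linear in κ plus Gaussian noise;
default intercepts sit at the reported regional scales (minicolumn width
tens of μm, bundle spacing ~50 μm, …) and slopes are signed so that wider
minicolumns/bundles accompany larger AngleR. `noise_sd_for_planted_spearman`
inverts the Gaussian-copula relation ρ_s = (6/π) asin(ρ/2) to plant a
target population Spearman. Age is drawn per group (≈70 ± 11 y); disease
duration exists for cases only and is linearly linked to age (r ≈ 0.88 by
construction). Every stochastic quantity takes an explicit seed; nothing
uses global RNG state.

What the generator does **not** emulate: gyral folding, partial-volume and
CSF contamination, spatially varying SNR, per-layer depth profiles of
diffusivity, or any histology image content (only scalar measures are
synthesized). Passing phantom tests therefore demonstrates correctness of
the estimation and aggregation machinery under the model's assumptions, not
fidelity to real cortical tissue.

## Cohort statistics

Spearman correlation is the Pearson correlation of average ranks, with the
two-sided t approximation t = r√((n−2)/(1−r²)) on n−2 df (|r| = 1 → p = 0);
exact permutation p-values are not attempted at these n. Missing values are
deleted pairwise (controls lack disease duration by design). The FDR
adjustment is the Benjamini–Hochberg step-up — sort ascending, q(i) =
n·p(i)/i, cumulative minimum from the largest rank, cap at 1, map back; ties
share their best rank's value. The reference publication cites the
Benjamini–Yekutieli variant, but its printed adjusted values are reproduced
exactly by plain BH (e.g. 90·0.001/3 = 0.030, 90·0.002/4 = 0.045, and the
0.050–0.056 run collapsing to 0.336 through the cumulative minimum), so BH
is implemented; one printed entry (MD × microsegment number in the
prefrontal region, raw p = 0.233 → printed 0.7489) equals n·p/rank *without*
the monotonicity step (strict value 0.70548) and is documented as an
inconsistency of the printed column. Worth noting: the battery's 90 tests
reuse the same per-region metric and histology vectors, and under that
dependence the step-up procedure bounds the expected false-discovery
proportion but not the family-wise chance of some null rejection — the
scenario the conservative BY variant addresses (measured ≈0.10 on simulated
null cohorts).

Partial correlation uses the first-order recursion r_xy·z =
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) with t on n−3 df; Pearson-based by
default with a Spearman (rank-first) variant, since the original choice is
unstated. The mixed repeated-measures ANOVA is the classical split-plot
decomposition: the between-subject factor is tested against
subjects-within-groups (df g−1, N−g) and the within-subject effects against
region × subject(group) (df r−1, (r−1)(N−g)); for 9 + 6 subjects and 3
regions this yields the F(1, 13) and F(2, 26) strata. No sphericity
correction is applied by default, matching the uncorrected reported dfs;
the decomposition is verified against an independent implementation in the
tests. Paired t tests refuse zero-variance differences rather than emitting
infinite statistics.

## Problem sizes and determinism

Test and reference computations run at desk scale: 24³–48³ slabs, an 84³
annulus, cohorts of 15 subjects at 20³, 500-replicate sign-recovery and
200-replicate null-calibration simulations — all seeded, completing in a
few minutes total. Pipelines rerun with identical configuration and seeds
produce byte-identical CSVs; run logs record version, config hash, seed,
and per-stage counts (no timestamps).

## Known limitations

- The empirical correlation coefficients, group means, and F/t values of
  the reference study depend on unpublished postmortem data; only the FDR
  arithmetic, the df structure, and analytic/synthetic properties are
  reproducible here.
- Equivalence with the original proprietary profile-generation software
  cannot be asserted; the Laplace formulation is this package's own
  realization of the same idea.
- Accuracy claims against smooth-geometry closed forms exclude the
  one-to-two voxel boundary shell, where binary labels cannot localize the
  surface; applications should treat boundary-adjacent voxels as
  partial-volume suspects regardless.
- Single-tensor, single-shell only; no eddy-current/motion preprocessing,
  no multi-shell or non-Gaussian models, no surface meshes or histology
  image simulation.
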