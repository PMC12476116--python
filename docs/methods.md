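# Methods

This note documents the statistical models implemented in `crpmap`, the
synthetic data they are exercised on, the defaults and numerical choices,
and what the test suite does and does not establish.

## fALFF

For a voxel time course x(t) sampled at TR seconds, the one-sided FFT
amplitudes |X_k| are summed over bins with f_low ≤ f_k ≤ f_high (default
0.01–0.1 Hz, edges inclusive) and divided by the sum over all
positive-frequency bins up to Nyquist; the DC bin is excluded from both
sums, so raw fALFF ∈ [0, 1].  A `spectrum="power"` switch forms the same
ratio on |X_k|² for users who prefer the power-spectral convention; the
amplitude convention is the default.  Each subject's map is standardized by
its within-mask mean, giving a map with in-mask mean 1 that is invariant to
the overall signal scale.

Linear detrending is available (`detrend=True`) but off by default: drift
removal belongs to preprocessing, the DC exclusion already removes the
mean, and the least-squares trend of a finite oscillatory record is not
exactly zero — detrending a clean in-band sinusoid smears ≈7 % of its
amplitude mass across the spectrum and biases the ratio, whereas with
`detrend=False` an in-band sinusoid scores exactly 1 and an out-of-band
sinusoid exactly 0.  A constant series has zero spectral mass and is
defined to score 0 (with a warning).

## Voxelwise inference

The subjects × voxels panel is regressed voxel-by-voxel on
[1, CRP, covariates] by OLS; the statistic is t = β̂_CRP/SE(β̂_CRP).
Covariates are age, sex, education and mean framewise displacement for
fALFF, and age, sex, education for diffusion panels; BMI, antidepressant
type and illness duration can be appended for sensitivity fits.  Designs
are checked for rank and the offending collinear columns are named.

Family-wise error control is by permutation throughout, with the
**Freedman–Lane** scheme for nuisance covariates: the reduced
(nuisance-only) model is fitted once, its residuals are row-permuted, added
back to the reduced fit, and the full model is refitted.  Two one-sided
analyses are run, one per contrast sign, mirroring how positive and
negative CRP associations are reported separately.

* **Cluster-extent FWE** (volumetric fALFF): clusters form where the
  one-sided t exceeds the cluster-defining threshold (default voxel
  p = 0.001), 26-connectivity; the null is the permutation distribution of
  the maximum cluster extent per sign, and
  p_FWE = (1 + #{max_null ≥ size})/(n_perm + 1).
* **TFCE-FWE** (skeleton panels): TFCE(v) = Σ_h e(h,v)^E h^H dh with
  E = 0.5, H = 2 (the de-facto standard exponents), integrated on an
  ascending threshold ladder with dh = max|t_obs|/n_steps (default
  n_steps = 100; permutation loops use coarser ladders for speed — the
  ladder from the observed map is reused across permutations so scores stay
  comparable).  Connected components are found by union-find over an
  arbitrary adjacency list (26-neighbor lattice edges for volumes, the
  supplied skeleton adjacency otherwise), compiled with numba.  The null is
  the per-sign maximum TFCE score; corrected p per voxel uses the same
  (1 + exceedances)/(n_perm + 1) convention.

The (1+·)/(n+1) convention counts ties as exceedances, which makes the
p-values valid (never anti-conservative) at any n_perm.  On very small
grids the max-cluster-extent null is heavily tied at extents of a few
voxels, so cluster-level p-values are discrete and markedly conservative
there (null rejection rates well below the nominal 5 % in the calibration
suite); this is a property of the discrete max statistic, not a fault of
the permutation scheme, and it fades on realistic grids where suprathreshold
extents spread over a wide range.

## Spatial association with annotation maps

The t-map is reduced to atlas regions (mean within region), and correlated
with each region-level annotation map using partial Pearson correlation
with the gray-matter probability vector partialled out of both sides
(partial-volume control).  Significance uses **variogram-matched
surrogates** of the phenotype map: smooth Gaussian fields over the region
centroids (exponential kernel) are generated at several candidate length
scales, the scale whose surrogate variograms best match the observed map's
binned semivariogram is selected, and the observed values are rank-remapped
onto each field.  Every surrogate is therefore an exact permutation of the
observed values that approximately preserves spatial autocorrelation.  A
parcel-rotation ("spin") null is not applicable because the parcellation is
volumetric rather than spherical; the surrogate strategy is pluggable.  The
permutation p is two-sided on |r|; BH-FDR is applied separately per map
family (neurotransmitter-like and behavioral-term-like), matching how the
two families are reported.  The test suite demonstrates on synthetic smooth
fields that freely shuffling region labels instead (the naive null) is
anti-conservative.

## Transcriptome association

Gene scores are Spearman correlations (default; Pearson available) between
each gene's regional expression and the phenotype map.  **Ensemble GCEA**:
a category's observed score is the mean member-gene score; its null
distribution rescores the *same* members against each surrogate phenotype,
re-using the real expression matrix so both spatial autocorrelation (via
the surrogates) and gene–gene co-expression (via the real matrix) are
respected.  Categories below `min_size` (default 5) are skipped with a log
entry.  The ensemble p is two-sided by default (one-sided per direction
available).  With a degenerate identity ensemble (all surrogates equal to
the phenotype) every null draw ties the observed score, so p = 1 — the tie
convention is honored even in this corner.

**PLS**: the first partial-least-squares component of genes → phenotype
(computed via scikit-learn, verified in the tests against the SVD of the
standardized cross-covariance).  The component correlation r is
sign-aligned to be non-negative; its permutation p refits the component
against each surrogate phenotype.  Strongly contributing genes are selected
under a shared budget of floor(0.25 · n_genes) ranked by |loading| and then
split by loading sign into PLS+ and PLS− — with 5013 genes this budget is
1253 genes in total, consistent with reported PLS+/PLS− set sizes that sum
to a quarter of the gene panel.  A per-gene scaled robust sigmoid
normalizer is provided for raw matrices; the module otherwise assumes an
already-normalized region × gene input.

## Clinical statistics and mediation

Two-sample t-tests (pooled or Welch) accept either raw vectors or printed
group summaries, so published demographic tables can be checked directly.
The 2×2 sex comparison uses Pearson χ² without continuity correction.
Partial correlations residualize both variables on the covariates; p comes
from the t distribution with df = n − 2 − k, and BH-FDR is applied over
each declared family with per-pair listwise deletion (clinical variables
have uneven missingness, so n varies by row).  Two independent
correlations are compared with Fisher's z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

Mediation fits three OLS equations (mediator on X, outcome on X + M,
outcome on X), each including the covariates; all paths are unstandardized
coefficients and c = c′ + a·b holds exactly on any complete-case sample.
The indirect effect a·b gets a percentile bootstrap CI (default 5000
resamples; percentile rather than bias-corrected, matching the current
default of the standard macro); significance is CI excluding zero.

## Synthetic data

The generator's defaults emulate the study conditions the pipeline was
designed around: 120 patients and 118 controls; CRP log-normal with
μ = −0.513, σ = 0.993 on the log scale (mean 0.98, SD 1.27 mg/L) clamped to
the observed assay range 0.02–6.39 mg/L; age, sex ratio, education, BMI
and framewise displacement drawn from the published group summaries.  The
standardized log-CRP latent `crp_z` drives every planted effect (the mg/L
clamp only affects the printed concentration).

Planted structure, patients only:

* **Mediation**: M = a·X + √(1−a²)·ε with a = 0.5; clinical outcome
  Y = c′·X + b·M + covariate effects + noise with b = 0.5, c′ = 0, so the
  population indirect effect is a·b = 0.25.
* **BOLD**: each in-mask voxel is white noise plus a 0.05 Hz sinusoid with
  random phase.  Inside the planted 3×3×3 cluster the amplitude is
  amp_base·exp(amp_gain·u); by default the driver u *is* the mediation
  latent M, which makes extracted cluster fALFF a valid mediator end to
  end.  Setting `beta_crp_falff` explicitly replaces the driver with an
  independent one at that CRP correlation (decoupling imaging effect size
  from the mediation paths).  amp_base = 1.5, amp_gain = 0.7,
  noise_sd = 0.25 were chosen so that the measured per-voxel fALFF–CRP
  correlation matches the planted target within the generator's ±0.1
  recovery contract (residual attenuation ≈ 0.03 from fALFF estimation
  noise at 200 timepoints); the grid default is 24³ voxels, TR 2 s,
  200 timepoints, which resolves the 0.01 Hz band edge.
* **Skeleton**: a 1-D chain of 300 voxels with smooth subject noise and a
  contiguous 40-voxel strip carrying a shared driver correlated with CRP at
  `beta_crp_ad` (default −0.5, axial-diffusivity-like decrease).
* **Expression**: genes are Gaussian random fields over the atlas
  centroids with exponential covariance (length scale 30 mm), so gene maps
  are spatially autocorrelated; the planted category's 15 genes are noisy
  copies of a designated phenotype pattern; 23 further categories of
  random size 8–30 are drawn from the remaining pool (≥ 20 categories in
  total, mirroring a GO-style table at desk scale).
* **Annotation maps**: smooth random fields, with designated maps mixed
  with the phenotype at a stated correlation (default plant r = 0.6).
* **Atlas**: a random Voronoi parcellation (default 60 regions) standing
  in for a ~250-region volumetric atlas at desk scale, with a per-region
  gray-matter probability vector.

The generator is bit-deterministic given its seed.  It does **not** emulate
hemodynamics, scanner artifacts, registration error, realistic white-matter
geometry, donor-level transcriptome assembly, or between-subject variation
in the annotation atlases — so passing tests show that the *statistical
machinery* recovers planted effects under idealized noise, not that the
pipeline is robust to real acquisition artifacts.

## Problem sizes and runtime

The calibration suites use 200 null cohorts × 500 permutations on a 6³
grid / 150-voxel chain with n = 30 (a scale at which the permutation
engines run in well under a millisecond per fit); cluster recovery runs at
the full default cohort and grid; mediation recovery uses n = 2000 and CI
coverage 300 replicates at 1000 bootstrap resamples.  The acceptance
script uses 100 null cohorts per modality and 200 coverage replicates.
These sizes were chosen so the whole suite completes in a few minutes on a
single CPU while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Cluster-level inference on very small grids is conservative (see above).
* The surrogate generator matches the variogram through a single
  exponential length scale; maps with strongly anisotropic or multi-scale
  autocorrelation are only approximately matched.
* The PLS permutation test permutes the phenotype side only; gene-side
  resampling is out of scope.
* Simple mediation only (one mediator, no moderation, no SEM), matching
  the analysis it implements.
* MRI preprocessing (realignment, normalization, skeleton projection) and
  donor-level transcriptome preprocessing are out of scope; the pipeline
  starts from analysis-space panels and a processed region × gene matrix.
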