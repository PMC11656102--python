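# Methods

## The problem

ROI volumetry from multi-atlas label fusion (MALF) treats each subject's
volume estimate as equally reliable, but segmentation precision varies
across subjects: a target image that aligns poorly with the atlas pool
(because of disease-related morphology, noise, or motion) yields fused
segmentations that depend strongly on *which* atlases were used.
`atlasboot` quantifies that dependence per subject and feeds it into a
heteroskedasticity-aware group comparison.

## Model

For subject *i* with target image *T_i*, covariates *X_i* and fused ROI
volume estimate *Y_i*, assume

    Y_i = X_i' beta + eps_i,    E[eps_i | T] = 0,
    Cov(eps | T) = diag(sigma_1^2, ..., sigma_n^2),

i.e. errors are uncorrelated given the target images, with subject-specific
conditional variances driven by the segmentation procedure.  Weighted least
squares with weight matrix `W = diag(w_i)` has the closed form
`beta_hat = (X'WX)^{-1} X'WY`; it is unbiased for any positive weights, and
by Aitken's theorem the choice `w_i = 1/sigma_i^2` minimizes the variance
of every coefficient estimate.  The package estimates `sigma_i^2` by
bootstrapping the atlas collection: resample the atlas pool with
replacement, re-fuse each resampled collection, extract the ROI volume,
and take the unbiased sample variance across replicates.  Its reciprocal is
the subject's precision weight.  The reciprocal coefficient of variation
(replicate sd / replicate mean) is provided as a comparison scheme.

## Fusion engines

The bootstrap is fusion-agnostic; any MALF engine can supply the replicate
volumes (externally computed replicate tables are accepted through the
"statistical route" CSV input).  Two built-in engines make the imaging
route self-contained:

* **Majority vote** — each voxel takes the label endorsed by the most
  atlases.
* **Locally weighted vote** — atlas *a*'s vote at voxel *v* is weighted by
  `exp(-SSD_a(v) / (h * |patch|))`, the sum of squared intensity
  differences to the target over the cubic patch of radius `patch_radius`
  (default 1, i.e. 3x3x3) centred at *v*.  Patches are clipped at image
  borders and the SSD normalized by the clipped patch size, which avoids
  padding conventions.  The bandwidth `h` defaults to the sample variance
  of the target intensities, making the weights invariant to global
  intensity rescaling in a scale-adaptive way.

Both engines are deterministic; ties are broken toward the smallest label
id so results are reproducible across platforms.  An empty fused ROI is
legal and yields volume 0 (flagged downstream as `empty_roi`).

Because vote weights do not depend on which collection was drawn, a
bootstrap replicate reduces to an integer-multiplicity-weighted tally over
the atlas pool; this makes thousands of replicate fusions cheap without
changing the procedure.

## Bootstrap settings

* `n_replicates` defaults to 300.  The running-variance diagnostic
  (`running_variance_curve`) tracks the sample variance of the first *n*
  replicates; on the phantom scenes used in the test suite the curve at
  n = 300 is within 20% of its n = 1000 value for ≥ 9 of 10 seeds.
* `collection_size` defaults to the pool size (same-size bootstrap).
* Degenerate collections (one atlas filling every slot) are kept:
  excluding them would bias the variance.
* A variance floor (1e-9 mm^6) and CV floor (1e-6) cap the weights on
  degenerate zero-variance inputs, with a warning and a `zero_variance`
  flag; they never bind on realistically noisy data.
* Per-subject random streams derive from (global seed, CRC32 of the
  subject id), so subjects may be processed in any order or in parallel
  with identical output.

## Permutation inference

Because the weights are estimated, p-values come from permutation rather
than the t reference distribution.  The primary procedure is the weighted
Collins–Dekker (Smith) method: residualize the predictor of interest
against the nuisance covariates by WLS, permute those residuals to build
surrogate predictors, and record the full-model WLS t-statistic of each
surrogate.  The weighted Freedman–Lane procedure (permute the reduced-model
response residuals and add back the fitted values) is provided as a
secondary route; on null data the two agree within Monte Carlo error.

Numerical/interface choices:

* The two-sided p-value pools the observed statistic with the permuted
  ones: `p = (#{|t*| >= |t_obs|} + 1) / (n_perm + 1)`, so `p >= 1/(n_perm+1)`
  and the test is valid by construction.  Ties in |t| count as
  exceedances (conservative).  A `counting="strict"` option replaces `>=`
  with `>` and drops the pooled observed statistic.
* `n_perm` defaults to 999, i.e. 1000 statistics altogether with the
  observed one.
* Permutations are drawn uniformly with replacement from the permutation
  group (not guaranteed distinct); `exhaustive=True` enumerates all n!
  permutations for small n and returns the exact p.
* The t-statistic uses the classical WLS standard error
  `sigma2 (X'WX)^{-1}` with `sigma2 = sum w_i r_i^2 / (n - p)`, consistent
  with treating the weights as inverse error variances; permutation
  inference makes the p-value insensitive to this choice.  The residuals
  permuted in the Collins–Dekker step are the raw residuals of the
  weighted reduced fit (not re-weighted); this is one reasonable reading
  of the weighted procedure and is validated empirically by the null
  calibration below.
* Permutation fits are vectorized through the Frisch–Waugh–Lovell identity
  in sqrt(w)-scaled coordinates, which reproduces the per-permutation full
  WLS t exactly (checked against looped fits to 1e-15).
* Everything is invariant to rescaling all weights by a positive constant,
  exactly; with unit weights both procedures reduce to their standard
  unweighted forms and WLS reduces to OLS.

## Simulation designs

`type1_experiment` draws `2n` subjects without replacement from a single
pool and assigns artificial 0/1 labels at random (n per group), so the
null holds by construction; covariates and weights travel with the
subject.  `power_experiment` draws `n` subjects with replacement from each
of two pools; duplicated subjects are treated as distinct observations.
Both adjust for age and ICV by default and use strict `p < alpha`
rejection.  `alpha` may be any value in (0, 1].

## Synthetic data

The phantom generator emulates a registered atlas pool: the ground truth
is a voxelized ellipsoid, the target intensity is the smoothed truth plus
Gaussian noise, and each atlas is the truth translated by a per-axis
Normal(0, `shift_sd`) mm displacement (nearest-voxel resampling, so labels
stay integral) with boundary labels flipped at `label_flip_rate`.  The
translation magnitude stands in for registration uncertainty: the mean
bootstrap variance is non-decreasing in `shift_sd` (verified over 20 seeds
per shift level).  What it does *not* model: deformable misregistration,
bias fields, motion artifacts, correlated atlas errors, multi-label
anatomies.  Passing tests therefore demonstrate the statistical machinery,
not segmentation accuracy on real MRI.

The cohort generator draws subjects from the heteroskedastic linear model
above with age ~ Uniform(55, 95) years, ICV ~ Normal(1.4e6, 1.2e5) mm^3,
and error sd `sigma_i = base_sd * LogNormal(0, lognormal_sd)`
(defaults 100 mm^3 and 0.5).  The default coefficient vector
(7400, 10, 0.001) for (intercept at age 75, age, ICV) centres volumes in
the high single-digit cm^3 range typical of hippocampal volumetry.
Outlier structure is group-specific: a configurable fraction of one
group's subjects get their volume shifted upward (+1000 mm^3 by default)
and their error sd inflated (factor 5), emulating poorly segmented scans
that produce high outlying volume estimates of low precision.  Hidden
truth columns (`true_sigma2`, `is_outlier`) expose oracle weights
`1/sigma_i^2`; the `noisy_weights` option replaces `sigma_i^2` with a
scaled chi-square draw at `n_boot - 1` degrees of freedom to emulate
bootstrap estimation error.  The per-subject CV is defined against the
subject's expected volume, mirroring sd/mean of replicates.

## Problem sizes used in validation

The test suite validates at desk scale: null calibration uses 1000
independent cohorts of 160 subjects with 999 permutations each; Aitken
efficiency uses 2000 cohorts of 160; the power-gain check uses pools of
200 + 200 subjects with 300 replicates on the per-group grid (20, 40, 60);
phantom checks use 16x16x12 grids with 10 atlases and 100–1000 bootstrap
replicates.  The power-gain scenario freezes a modest negative group
effect (-300 mm^3) against +1000 mm^3 variance-inflated outliers at rate
0.2 in the case group; a back-of-envelope calculation shows the outlier
shift nearly cancels the effect for OLS while oracle precision weights
suppress the outliers' influence to ~1%, so the weighted-vs-unweighted
power gap is expected to be large.

## Known limitations

* The bootstrap captures only across-atlas-collection variability, not
  scan–rescan variability of the same subject.
* Conditional uncorrelatedness is assumed; correlated-error (GLS) models
  and multi-ROI covariance weighting are out of scope.
* Phantom misalignment is rigid translation plus boundary noise; it is a
  phenomenological stand-in for registration error, not a registration
  simulator.
* Weights estimated from a finite bootstrap carry estimation error; the
  permutation test remains calibrated (its validity does not rest on the
  weights being the true inverse variances), but efficiency degrades
  gracefully with weight noise.
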