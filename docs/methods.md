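# Methods

`mtlnet` re-implements, on synthetic data with known ground truth, a
seed-based analysis of the two medial temporal lobe (MTL) functional
systems: the anterior-temporal (AT) network, hubbed on the perirhinal
cortex (PRC), and the posterior-medial (PM) network, hubbed on the
parahippocampal cortex (PHC).  The pipeline derives data-driven AT/PM
network masks from resting-state BOLD, reduces each scan to two scalar
connectivity indexes, and models those indexes against age, Alzheimer's
stage, biomarkers and time to dementia onset.  Because the reference
cohort is not publicly deposited, every input here is synthesised; the
generator's planted parameters are the ground truth that the statistical
stage must recover.

## Synthetic data

### Table mode

`synthgen.generate_cohort` emits a long-format per-visit table for six
groups — cognitively unimpaired young (19.5–40 y), middle-aged (40–60 y),
older amyloid-negative and amyloid-positive adults (60–85 y), MCI and
AD-dementia patients — with default sizes 90/55/56/8/26/26 (261
participants; the young/middle split of the pooled 145 unimpaired adults
is the package's choice and reproduces their pooled mean age of ~37 y).
Each subject contributes 1–3 visits spaced 18 ± 4 months.  Demographics,
MMSE/MDRS ranges, amyloid and FDG SUVR distributions, hippocampal volumes
and group-shifted mean framewise displacement are drawn from truncated
normals matched to the reference cohort's group summaries; 18 of 26 MCI
patients are converters with dementia onset uniform over 6–85 months.

The connectivity indexes are generated as
`index = planted linear predictor + N(0, noise_sd)`:

| effect | default | scale |
|---|---|---|
| AT age slope | +0.0003 | z / year |
| PM age slope | −0.0007 | z / year |
| AT stage offsets (MCI, AD) | +0.0416, +0.0375 | z vs older controls |
| AT amyloid slope | +0.1601 | z / SUVR |
| AT FDG slope | −0.1013 | z / SUVR |
| AT hippocampal-volume slope | −0.0694 | z / SD of normalized volume |
| AT MMSE, MDRS slopes | −0.0047, −0.0018 | z / point |
| AT delay-to-onset slope (converters) | −0.0136 | z / month |

Predictors are centred at fixed references (SUVR 1.31, FDG 1.0, MMSE 29,
MDRS 140; hippocampal volume standardized with fixed constants), so the
mapping is exactly linear and invertible: with `noise_sd = 0`, ordinary
least squares on the planted design recovers every coefficient to machine
precision (tested).  The hippocampal effect is planted on a *standardized*
normalized-volume scale because the raw normalization `raw/(TIV × 1000)`
produces values of order 10⁻⁶, on which a coefficient of −0.07 would be
meaningless.  The within-subject visit-to-visit noise `noise_sd = 0.05`
is a free parameter of the generator (no empirical value is available for
it) and all power statements downstream are conditional on it.

### Image mode

`synthgen.generate_run` synthesises a 4D BOLD run (default 20×20×12
voxels of 3 mm, 120 volumes, TR 2.382 s) with four disjoint cuboid ROIs:
PRC and PHC seeds, and AT and PM network blocks.  Each seed carries a
unit-variance latent series; each network voxel is
`λ·latent + √(1−λ²)·noise`, so the population correlation between the
seed-mean series and every network voxel equals the loading λ exactly.
Nuisance structure — per-voxel linear drift, a global signal, WM/CSF box
signals, and motion-coupled regressors driven by a random-walk motion
trace — is added on top, scaled by `nuisance_scale`.  Calibration tests
run at `nuisance_scale = 0` (the correlation contract is for the latent
signal; the nuisance exists to be removed by preprocessing, and the
preprocessing tests verify that it is).  Segmentations are box-shaped
probability maps with a T2* dropout pocket away from the networks; a
four-label parcellation splits each network into two slabs.

What image mode does *not* emulate: anatomy, susceptibility geometry,
slice timing, realignment error, spatially correlated physiological
noise, or between-subject anatomical variability.  A green image-mode
test therefore establishes the correctness of the numerical pipeline
(filtering, regression, correlation, inference, extraction), not its
robustness to real-scanner artefacts.

## Image pipeline

* **Motion QC** excludes scans with maximum |translation| > 3 mm or mean
  absolute Euler rotation angle (norm of the three rotations) > 1.5°.
* **Framewise displacement** uses the displacement convention
  `FD_t = Σ |Δp|` with rotations converted to arc length on a 50 mm
  sphere; FD of the first frame is 0.
* **Bandpass** is a voxelwise linear detrend followed by an FFT mask
  retaining 0.01–0.08 Hz (inclusive).  An FFT mask rather than a
  Butterworth filter keeps an analytic pass/stop contract that the tests
  assert exactly.  The order of operations is fixed: 4 mm spatial smooth →
  bandpass → confound extraction from the filtered run → OLS confound
  regression, with confound columns bandpassed identically so the
  regression cannot reintroduce out-of-band power (asserted ≤ 1%).
* **Confounds**: WM/CSF means over voxels with tissue probability ≥ 0.9
  (strict to avoid partial-volume contamination; configurable), global
  mean over the brain mask, their first differences (leading 0), and the
  six motion parameters.  Exactly-collinear columns are dropped with a
  warning, first occurrence kept.
* **Connectivity**: analysis voxels are `gm_t1 ≥ 0.25 AND gm_t2star ≥
  0.25` — the two thresholded maps are *intersected* because the mask
  exists to exclude dropout voxels (union would re-admit them; a union
  option exists).  Pearson r between the seed-mean series and every
  in-mask voxel, Fisher z = atanh(r) with |r| clipped at 0.999999;
  negative r values are retained in maps (one-sided inference and
  positive-voxel extraction make them immaterial downstream).  Group maps
  are smoothed at 6.3 mm FWHM (σ = FWHM/2√(2 ln 2), truncated at 4σ,
  reflective boundaries); index extraction always uses unsmoothed maps
  and a smoothed input is a hard error.

## Permutation inference and masks

TFCE integrates cluster extent^E × height^H over 100 thresholds
(dh = max/100), with E = 0.5, H = 2 and 26-connectivity (the cited
tool's defaults; none are stated in the source description).  The
implementation is an incremental threshold-descending union-find
(numba-jitted when numba is available, with an identical scipy
per-threshold fallback); tests pin both paths to a brute-force BFS
oracle at 1e−8.

One-sample tests use sign-flip permutations of subject maps with the
image-wide maximum of TFCE(t-map) as the null statistic;
`p_FWE(v) = (1 + #{null_max ≥ TFCE_obs(v)}) / (n_perm + 1)`, one-sided
(greater).  Sign flips are enumerated exhaustively when `2^n ≤ n_perm`.
Voxels with exactly zero variance get t = 0 when their mean is ≤ 0 and a
large finite t when positive (a constant positive offset is infinitely
significant; the finite stand-in keeps TFCE well-defined).  Paired tests
run the same machinery on per-subject difference maps.

Masks: `AT = sig(PRC one-sample) ∩ sig(PRC > PHC)` and
`PM = sig(PHC one-sample) ∩ sig(PHC > PRC)` at α = 0.05.  The AT rule is
read as an intersection by symmetry with PM's stated overlap; a union
option is exposed.  The opposite one-sided paired contrasts make AT and
PM disjoint by construction.  Participant-specific masks intersect the
group mask with the subject's GM (≥ 0.5) and remove seed voxels to
prevent autocorrelation; the network index is the mean of strictly
positive Fisher-z values in that mask (missing if none).  Parcellation
ROIs keep label intersections with ≥ 100 voxels (inclusive).

**Mask-recovery geometry.**  The recovered mask is inevitably the planted
network plus a halo of roughly two voxels: 6.3 mm smoothing carries
signal across the blob boundary, and TFCE's extent term drags any
adjacent voxel with moderate t into the blob's cluster.  Dice against
the planted network is therefore bounded by the blob's surface-to-volume
ratio — ≈ 0.6 at the 20×20×12 demo grid no matter how strong the
loading.  The recovery benchmark consequently runs on a 36×26×18 grid
whose planted networks are large relative to the kernel (as real
networks, spanning ~10⁵ mm³, are relative to 6.3 mm), where Dice ≈ 0.79
at loading 0.8 with n = 20 and 500 permutations.

## Statistics

All longitudinal models are linear mixed models with a by-participant
random intercept, fitted by REML.  The variance ratio θ = τ²/σ² is
profiled (per-subject covariance `σ²(I + θJ)` inverted by
Sherman–Morrison), making estimation a 1-D optimisation; with one
observation per subject only σ²(1+θ) is identified and the fit resolves
to the OLS corner θ = 0.  Fixed effects carry Satterthwaite-approximated
degrees of freedom: the variance of the REML variance estimates is the
inverse observed information (finite-difference Hessian of the analytic
REML log-likelihood, one-sided at the τ² = 0 boundary), and the df of a
contrast follows by the delta method; multi-df F-tests combine
per-eigencontrast dfs in the usual way.  statsmodels' MixedLM reproduces
the point estimates and standard errors and serves as the independent
cross-check in tests; it is not used in the implementation because it
does not expose Satterthwaite F-tests.  Replicate simulations put the
95% CI coverage of planted slopes at ~93–95%.

Covariate coding: sex as a 0/1 indicator, education in years, age
centred at the sample mean.  Type II Wald F-tests (treatment coding) are
used for additive models; models with interactions use sum-to-zero
contrasts and Type III tests, and the spec of each model enforces this
pairing.  Exactly aliased design columns (e.g. a factor constant within
an analysed subgroup) are dropped with a warning.

The ranked-group trajectory model codes the six groups 1–6 along the
age/Alzheimer's continuum and fits a cubic penalized regression spline
(basis dimension k = 6) with an integrated-squared-curvature penalty,
whose null space is exactly the linear functions, under a sum-to-zero
identifiability constraint.  The smoothing parameter is selected by REML
(the penalized block as a random effect): with only six distinct rank
values, GCV demonstrably undersmooths (effective df ≈ 4 on linear truth)
while REML recovers edf = 1.0 on linear truth and > 1.5 on curved truth.
Reported edf excludes intercept and covariates, so 1 means linear —
mgcv's convention.

Baseline stage differences use ANCOVA with estimated marginal means
(group predictions at covariate means) and unadjusted pairwise t-tests
(post hoc convention).  The biomarker/cognition association family —
2 networks × 5 features = 10 time-adjusted mixed models — is corrected
with step-down Holm–Bonferroni as one family; an exact brute-force
oracle pins the implementation.  Amyloid status uses the 99.9th
percentile (linear-interpolation convention) of a young-adult SUVR
sample as threshold; with no baseline PET, a subject is negative only if
all later scans are sub-threshold, and `undetermined` otherwise rather
than guessing positivity backwards in time.

## Numerical choices and degenerate inputs

* Permutation p-values are +1-smoothed, so `p ≥ 1/(n_perm+1)`; `n_perm <
  100` warns.
* Dice of two empty masks is defined as 1.0 with a warning; an empty
  participant mask yields a missing index, not an error.
* `fisher_z` clips |r| at 0.999999, keeping z finite for r = ±1.
* A constant outcome short-circuits the LMM with a `degenerate` flag.
* Gaussian smoothing treats NaN as missing and renormalises by the
  smoothed validity mask, so missing markers neither leak nor attenuate
  neighbours.
* All stochastic stages derive per-stage seeds from one run seed by
  hashing, keeping every derived seed below 2³¹.

## Known limitations

* Synthetic geometry is cuboid; there is no test of anatomical
  plausibility, inter-subject misalignment, or parcellation realism.
* Satterthwaite coverage is approximate (~93–95% in replicates at the
  cohort sizes used); conclusions that hinge on a coefficient sitting
  exactly on a CI boundary are fragile at this n.
* The FD-adjusted and both-network variants reuse the same confound and
  stacking machinery but are exercised at smoke-test depth only.
* Image-mode cohorts are cross-sectional (one visit per subject); the
  longitudinal structure is exercised in table mode.
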