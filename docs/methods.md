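# Methods

This note documents the models and procedures the package implements, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pattern distance and the within-participant test

An event's multivoxel pattern is the mean over a 5-TR window centred on
the event's middle TR; the middle TR follows the 1-based field convention
`round((onset + duration/2) / TR)` and is converted to 0-based indexing in
exactly one function (`drift.clip_middle_tr`). When the centred window
would extend past the start or end of the run it is shifted to stay
inside (erroring only if the middle TR itself is outside the run). Pattern
dissimilarity is `1 − Pearson r` across voxels, in `[0, 2]`; constant
patterns are an error, and regions under 10 voxels are recorded as
missing rather than analysed.

The within-participant statistic is the Pearson correlation between
per-interval pattern distances and the participant's duration estimates
over the retained (high-confidence, two-minute) intervals, Fisher
transformed (`atanh`, clamped at |r| = 1 − 1e-7). Its null distribution
comes from phase-randomized surrogates of the lagged distance time course:
the dissimilarity between the window-averaged pattern at each TR and the
pattern 80 TRs (2 min) later. Surrogates multiply each positive-frequency
Fourier coefficient by a random phase (conjugate-symmetric negative
frequencies; DC and Nyquist untouched), preserving the amplitude spectrum
to numerical precision. Each surrogate replaces the empirical series and
is sampled, for each retained interval, at the series index whose first
window is centred on the first clip's middle TR (indices clamped into the
valid range near the run edges); the mapping from intervals to series
indices is a design choice of this package — the source analyses leave it
implicit. The z-value uses the sample (n−1) standard deviation:
`z = (r_emp − mean(r_null)) / sd(r_null)`. Group inference is a
right-tailed one-sample t-test per region with two-stage
Benjamini–Krieger–Yekutieli FDR (statsmodels `fdr_tsbky`); the a-priori
region set is reported at q < 0.05 and whole-brain exploration at q < 0.1.

In the degenerate case of identical z-values across participants the t
statistic is defined as 0 (p = 0.5) when the common value is zero, ±inf
otherwise, rather than NaN.

## Within-interval test

Distances and estimates are z-scored within participant across that
participant's retained intervals, making the analysis invariant to any
per-participant affine rescaling of estimates. Per interval, the Pearson
correlation across the participants who retained it (minimum 3) is
compared with a null built by permuting the estimate-to-participant
assignment within the interval (10,000 by default; BOLD autocorrelation is
irrelevant across participants, so phase randomization is unnecessary
here). Effect size is Cohen's d = mean(r)/sd(r).

## Preprocessing

* **Despiking**: points deviating from the series mean by more than 5×IQR
  are replaced by cubic interpolation over surviving points
  (nearest-value at the edges). If more than half the points are flagged
  the series is considered pathological and an error is raised. A
  constant series (IQR = 0) passes through unchanged.
* **High-pass filter**: a Gaussian-weighted running-line fit (the FSL
  algorithm), implemented directly as a local-linear smoother matrix so a
  whole voxel×time matrix filters in one matmul; the matrix is cached per
  (T, TR, sigma). The filter is parameterised by cut-off period with
  sigma = cutoff/2, which reconciles a working sigma of 240 s with a
  selected 480 s cut-off. The residual is re-centred and the input mean
  re-added, so the output mean equals the input mean exactly. Two
  properties of this filter worth knowing: it is only *approximately*
  idempotent (repeat filtering moves points by ~2% of the SD — a
  local-linear smoother is not a projection), and its transition band is
  wide — a sinusoid at twice the cut-off period is attenuated to roughly
  0.7 amplitude, not removed. Both are properties of the named algorithm,
  verified in the test suite at honest tolerances.
* **Nuisance residualization**: every voxel is regressed on the mean of
  the top-1% highest-SD voxels, the mean CSF signal and the mean WM
  signal (plus intercept, which is retained so voxel means survive). It is
  intended to run after high-pass filtering. Note a structural
  consequence: the whole-CSF compartment mean is itself a regressor and
  its residual is exactly zero, so ISC diagnostics on CSF must use a
  sub-region (e.g. a ventricle mask) that is not identical to the
  regressor mask.
* **Cut-off selection**: for each candidate cut-off (140–720 s), the
  pipeline filters, residualizes, and computes leave-one-out inter-subject
  correlation (ISC) per region; the selected cut-off is the longest for
  which every designated grey region's ISC exceeds the CSF ISC in a
  paired one-tailed t-test at alpha = 0.05 (the significance criterion is
  this package's reading; the source describes the comparison but not the
  test). If none qualifies, the shortest candidate is returned with a
  warning.

## Searchlights and cluster-mass FWE

Cubic searchlights write the statistic of the cube∩mask voxel set to the
centre voxel. The side-3 (27-voxel) variant uses a strict-interior edge
rule; the side-5 (125-voxel) variant intersects with the mask and skips
centres with fewer than 25 voxels, and group maps mask out voxels
evaluated in fewer than 5 participants. Group inference: voxelwise
right-tailed one-sample t across maps, cluster-forming threshold p < 0.01,
26-connectivity labelling, cluster mass = summed supra-threshold t.
Sign-flipping of whole maps (the standard one-sample exchangeability
argument) yields the max-cluster-mass null; corrected
p = (1 + #{perm ≥ obs}) / (1 + n_perm), or the exact enumeration fraction
when 2^n_maps ≤ n_perm (deterministic for ≤ ~12 maps at the default
permutation counts). No variance smoothing is applied.

## Hierarchical regression

The model regresses Box-Cox-transformed duration estimates on an
intercept, the naive group's per-interval mean estimate, and the region's
neural pattern distance, with subject perturbations on all three
coefficients and interval perturbations on the intercept and distance
slope (the naive covariate does not vary within interval, so its slope
cannot). The Box-Cox exponent maximises the profile likelihood of the
fixed-effects-only model on a λ grid [−2, 2] step 0.01 (non-positive
responses error unless an explicit half-unit shift is enabled, which
warns). Covariates are standardised over the analysis set before fitting;
this stabilises the crossed fit and is recorded in the assembled data.

The optimiser is statsmodels' linear mixed model. Correlated crossed
random effects in the lme4 sense are not directly expressible there, so
the ladder of structures is: (0) correlated subject effects plus
independent interval variance components for intercept and distance
slope; (1) drop the interval distance component; (2) subject intercept
only plus interval intercept; (3) subject intercept only. A rung is
accepted when the optimiser converges with finite fixed-effect intervals
and an interior covariance; a converged boundary (zero-variance) fit is
kept as a fallback when no interior fit exists — the boundary estimate is
the data's message when group variability is negligible, which is also
where the regularising prior of the original fitting procedure would
land. The rung used is recorded in the fit object. 95% intervals are Wald
(asymptotic Gaussian); they are known to be anti-conservative for designs
with few clusters and large group variances, and the coverage calibration
in the acceptance suite is therefore run in a regime (12 subjects, 24
intervals, group SDs well below the residual SD) where the approximation
is expected to be accurate. An independent cross-check against R lme4's
crossed-formula fit on one dataset is part of the test suite.

## Timescale profiling

Three measures of a region's speed of signal change, all based on the
full width at half maximum (FWHM) of an autocorrelation function: the
multivariate ACF (pattern at each TR correlated with the pattern at every
lag, averaged over reference TRs, on 5-TR-smoothed data), the same after
OLS-regressing region size out of the participant's FWHM vector, and the
univariate ACF (per-voxel lagged autocorrelation averaged over voxels,
computed on the shrinking overlap with no padding). FWHM counts the lags,
over a symmetric evaluated range capped at ±T/4 (edge-noise bound; the
source is silent on the range), with mean ACF at or above half its
maximum — two-sided, so boxcar-smoothed white noise at width 5 gives
FWHM 5 and an AR(1) voxel with ρ = 0.9 gives 13. Regions are compared
with right-tailed paired Wilcoxon signed-rank tests and ranked by mean
FWHM.

## Behavioral statistics

Per-interval confidence is the minimum of the two clip ratings; the
confidence filter drops the lowest-confidence intervals subject to
dropping ≥ 1/3 and retaining ≥ 1/3, choosing among feasible thresholds
the one closest to an even split (the tie-break is this package's choice;
the source states only the two one-third constraints) and falling back to
retaining everything (with a warning) when no threshold is feasible.
Gap contrasts are paired t-tests on per-participant (6-min − 2-min) mean
differences. The bootstrap CI for a correlation with an interval covariate
resamples participants with replacement and uses the standard 2.5th/97.5th
percentile bounds (the source's percentile wording is internally
inconsistent for a 95% interval; the standard convention is used). The
difference between two correlations uses the combined-CI formulas
`lldiff = rdiff − sqrt((r1−ll1)² + (ul2−r2)²)`,
`uldiff = rdiff + sqrt((ul1−r1)² + (r2−ll2)²)`. Group reliability uses
leave-one-out ISC within and between equally sized groups with a
10,000-fold label-scrambling permutation test; split-half reliability
averages the correlation of half-group interval means over random splits
(odd n splits ⌊n/2⌋/⌈n/2⌉). The time-order analysis correlates each
participant's estimates with interval story position (2-minute intervals
by default, configurable). Timeline accuracy regresses estimated on
actual clip position per participant, so any affine distortion of a
participant's subjective timeline is absorbed; accuracy is the negative
absolute residual.

A caveat established during calibration and verified in the tests: the
participant-resampling percentile bootstrap for a correlation of a
participant-mean vector is biased toward zero when per-participant noise
is large relative to the shared signal (resampled panels double-count
noise), and its CI inherits the bias. Coverage is nominal in
moderate-noise regimes, which is where the coverage property is tested.

## Synthetic-data generator

Defaults are the emulated study conditions: 18 participants, 1040 TRs at
TR = 1.5 s, 43 intervals (24 at exactly 120 s, 19 at exactly 360 s)
delimited by 86 distinct 5–10 s clips with non-overlapping clip pairs,
estimates floored at zero with 1-s resolution.

Per region and participant the voxel signal is a sum of:

* a k-dimensional latent context walk (k = 12) — Gaussian steps smoothed
  over ~20 TRs then cumulated — projected through a fixed random loading
  matrix. A multi-dimensional latent (rather than a scalar) is what makes
  expected pattern dissimilarity increase monotonically with the Euclidean
  latent displacement between two time points; with a scalar latent,
  1 − r depends on the product of the two latent values rather than their
  difference. Half the walk variance is shared across participants (the
  story drives everyone's context) and half is idiosyncratic; the
  ground-truth displacement of an interval is the walk's Euclidean
  distance between the two clip middle TRs, recomputable from the seed.
* a stimulus-locked shared course (grey matter only) with positive-mean
  voxel loadings, giving grey regions inter-subject correlation;
* a global low-frequency artifact: 8 independent slow shared courses
  (power around/above 600-s periods, step size growing through the run)
  with voxel loadings that are shared across participants. More
  components than nuisance regressors means residualization is
  necessarily partial; accelerating steps reproduce the observation that
  unfiltered patterns everywhere, CSF included, drift apart later in the
  story;
* AR(1) voxel noise (φ = 0.3), with a small fraction (2%) of
  high-variance voxels carrying extra artifact — the population the
  top-SD nuisance regressor is meant to capture.

The default region set includes a drift region, a matched null region
(drift rate 0), WM and whole-CSF compartments, and a ventricle sub-region
for ISC diagnostics.

Behavioral estimates are
`base + slope·gap + effect_size·z(displacement) + content_effect·z(content
dissimilarity) + participant offset + noise`, with the displacement and
content terms z-scored *within* each true-gap group so the objective-time
sensitivity is carried by the gap slope alone (base 160 s, slope 0.5,
giving 2-/6-minute means near the observed ~3.7/5.7 min). Content
dissimilarity is 1 − r between per-clip feature vectors sampled from a
smooth story-time process (decay scale 180 s), so naive estimates —
content term plus a weak gap slope — have stimulus-only structure.
Confidence ratings discretise a latent per-clip memory strength;
low-strength intervals get extra estimate noise, reproducing the
better-accuracy-when-confident phenomenon. Event-boundary raters press
with probability proportional to the shared latent step size, linking
boundary counts to both context change and mean estimates.

What the generator does **not** emulate: hemodynamic convolution, head
motion, spatial autocorrelation within regions, realistic anatomical
geometry (regions are disjoint cubes on a grid), non-Gaussian BOLD noise
spectra, and any nonlinearity in how context change maps to duration
judgments (the linear form is a modelling choice — the emulated study
established a correlation, not a generative law). Passing tests therefore
demonstrate that the *procedures* are correctly implemented and calibrated
under a plausible generative model, not that the scientific effect exists
in real data.

## Problem sizes and determinism

All randomness flows from one master seed through named SeedSequence
sub-streams keyed by (stream, participant, region), so partial or parallel
regeneration is bit-identical. Calibration suites run at reduced but
pre-registered sizes chosen to finish comfortably on one CPU: 500 null
draws with 1000 surrogates for the type-I check; 200 replicate null
datasets for FDR and cluster-mass FWE (n_perm = 500, 12 maps of 8³
voxels); 100 replicates of the planted-effect recovery at 16 participants,
700 TRs, 120-voxel regions and a drift→estimate coupling chosen so the
latent displacement–estimate correlation is ≈ 0.5; 200 replicates at 12
subjects × 24 intervals for mixed-model CI coverage.

## Known limitations

* The surrogate-to-interval index mapping is a documented convention, not
  derived from the source analyses.
* Wald intervals for the hierarchical model are anti-conservative outside
  the calibrated regime; a parametric bootstrap is the natural extension
  and is not implemented.
* The interval random effects are variance components (no
  intercept–slope covariance); lme4's fully correlated crossed structure
  is approximated, as documented in the ladder.
* Searchlight analyses assume maps share a grid; registration to a common
  space is out of scope and pre-transformed maps are accepted as input.
* The cut-off diagnostic inherits the wide transition band of the
  running-line filter: a "removed" period is attenuated, not annihilated.
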