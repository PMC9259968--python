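# Methods

This note documents the models, numerical choices and limitations behind
`peraf`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external results.

## The PerAF metric

For a voxel time series x_1..x_n with mean μ = (1/n) Σ x_i,

    PerAF = 100 · (1/n) · Σ_i |x_i − μ| / μ   (percent)

i.e. the mean absolute deviation expressed as a percentage of the mean
signal level. Two properties define its behaviour and are asserted as
invariants:

* **scale invariance** — PerAF(c·x) = PerAF(x) for any c > 0, which makes
  the metric comparable across scanners and voxels despite the arbitrary
  units of BOLD intensity;
* **offset sensitivity** — PerAF(x + k) ≠ PerAF(x), because μ sits in the
  denominator. This is intrinsic to the metric, not a defect; it is why the
  preprocessing steps restore the voxel mean (below).

For an i.i.d. Gaussian series N(μ, σ²) the population value is
100·√(2/π)·σ/μ (since E|X−μ| = σ√(2/π)); with σ/μ = 0.02 this is ≈ 1.596 %.
This closed form is the main quantitative oracle for both the metric and
the synthetic generator.

ALFF is provided for comparison: the mean of the single-sided amplitude
spectrum over 0.01–0.08 Hz, computed from the plain (untapered)
periodogram so pure-sinusoid checks hold exactly. ALFF is homogeneous of
degree 1 in the signal (contrast with PerAF's invariance). fALFF is the
in-band amplitude sum over the total amplitude sum, in [0, 1]; it is
undefined (an error, not 0/0) for a constant series.

PerAF is computed full-band; no temporal band-pass filter is applied
before it. ALFF/fALFF use the 0.01–0.08 Hz resting-state convention.

## Temporal preprocessing

The pipeline assumes spatially aligned volumes and performs, in order:

1. **initial-volume discard** — default 15 volumes, dropped before any
   other step (magnetisation-equilibration convention of the replication
   preset);
2. **motion QC** — a subject is excluded iff any translation strictly
   exceeds 1.5 mm on any axis at any timepoint, or any rotation strictly
   exceeds 1.5°. The translation rule is the replication value; the
   rotation bound is this package's choice (the source protocol gives no
   number) set symmetrically at 1.5. Exactly 1.5 passes (strict
   inequality). Excluded subjects appear in reports but in no statistics;
3. **nuisance regression** — OLS of each voxel series on [intercept,
   white-matter mean series, ventricle mean series]. No motion-parameter
   regressors. Residuals get the original voxel mean added back: the
   regression centres residuals near zero, which would destroy the μ > 0
   denominator PerAF requires, so the pre-regression mean is retained.
   The same mean-restoration applies to the linear detrend that follows;
4. **linear detrend**, voxelwise, mean restored.

Spatial smoothing is applied to the PerAF **maps** (6 mm FWHM default,
σ = FWHM/2.3548 per axis converted to voxels via the affine), not to the
4D series — map-level smoothing is the common amplitude-analysis choice
and keeps the metric's per-voxel definition exact. Boundary handling is
reflective (edge-repeating), fixed for reproducibility. Smoothing runs on
the full grid, so voxels at the mask edge mix with the 0 sentinel outside
the mask; this is negligible for interior masks and documented for
transparency.

Degenerate voxels (temporal mean ≤ 1e-6 of the in-mask median mean) are
dropped from the map mask and counted, rather than producing huge
percentages.

## Group statistics and cluster-extent correction

The group contrast is a pooled-variance two-sample t-test per mask voxel,
df = n₁ + n₂ − 2, patients minus controls; swapping groups negates the map
exactly, and zero-variance voxels are flagged rather than infinite.
Suprathreshold voxels (two-tailed critical t at the voxel-level p, default
0.01) are grouped into connected components per tail — positive and
negative clusters never merge — under 18-connectivity by default
(6/18/26 configurable).

Two extent rules decide significance:

* **fixed replication rule** — size strictly greater than 40 voxels;
* **Monte-Carlo (AlphaSim-style)** — simulate null fields on the analysis
  mask, smooth at the map FWHM, threshold at the same voxel-level p, record
  the largest cluster per iteration, and return the smallest size m whose
  empirical exceedance probability P(max ≥ m) is ≤ the cluster alpha
  (default 0.05). A cluster is significant iff its size ≥ m.

The Monte-Carlo null has two forms. The default pipeline form simulates
the *t-statistic* itself: each iteration draws n₁+n₂ smoothed, per-map
standardised Gaussian subject maps and computes their pooled t-field,
thresholded at the t quantile. The simpler classic form (single Gaussian
z-field per iteration, normal quantile) is available when no group sizes
are given; at low degrees of freedom it is mildly conservative, because
low-df t-fields produce slightly smaller null clusters than Gaussian
fields at the matched voxel-level p. The t-field null is what the
family-wise-error calibration test exercises: across 500 pure-noise
cohorts the probability of any significant cluster stays inside the 95%
binomial interval around 0.05.

Smoothness for the null is taken as the FWHM applied to the maps;
data-driven smoothness estimation is out of scope. Peak coordinates are
reported in reference-space mm through the image affine (the grid is
0-indexed internally). Anatomical peak labels require a user-supplied
atlas; none is bundled.

## Discrimination

Features are per-subject mean PerAF over each significant cluster. Per
region, the ROC is the empirical curve over all thresholds; the trapezoid
AUC equals the normalised Mann–Whitney U statistic (ties counted ½), an
identity asserted to 1e-12. The score orientation is chosen so AUC ≥ 0.5
with the direction recorded (the planted effect makes patients lower).
Confidence intervals use DeLong's placement-value variance with a normal
approximation, truncated to [0, 1]; the implementation is cross-checked in
the tests against a frozen value from an independent reference
implementation. The operating point maximises the Youden index, ties
broken toward higher specificity.

The classifier is a linear soft-margin SVM (C = 1 default), evaluated by
leave-one-out: for each subject, features are z-scored using
training-fold statistics only, the SVM is fitted on the other N−1
subjects, and the held-out subject is predicted. Sensitivity, specificity
and accuracy come from the aggregated confusion counts (patient =
positive). The permutation test shuffles group labels and reruns the
entire LOO procedure — fold-wise z-scoring included — per shuffle;
p = (1 + #{null ≥ observed}) / (1 + n_permutations), so the smallest
achievable p at B shuffles is 1/(B+1). The replication preset uses 10,000
shuffles; tests and the acceptance script use 1,000 for speed.

## Synthetic cohorts

The generator emulates a two-group resting-state study: per voxel,
`baseline + band-limited Gaussian fluctuation + white noise`, with the
fluctuation amplitude multiplied by `effect_factor` inside spherical
effect ROIs for the patient group. Defaults (the study conditions every
calibration and recovery test runs under):

| parameter | default | rationale |
|---|---|---|
| grid | 24×24×24 voxels, 3 mm | desk-scale but large enough for >40-voxel clusters |
| TR / timepoints | 2 s / 245 | 230 remain after the 15-volume discard |
| band | 0.01–0.08 Hz | resting-state convention |
| baseline | 1000 | ≥ 10·(amplitude+noise): positivity without clipping |
| fluctuation σ | 20 (2 % of baseline) | typical resting BOLD fluctuation scale |
| white noise σ | 10 | noise_sd ≤ fluct_amplitude regime |
| effect ROIs | two disjoint r=3 spheres (123 voxels) | comfortably above the 40-voxel rule |
| effect factor | 0.5 | halved fluctuation amplitude in patients |
| spatial FWHM | 6 mm | realistic spatial coherence of the signal |
| subject amplitude CV | 0.10 | between-subject amplitude variability |
| n per group | 18 | two matched groups of 18 |

Band-limited signal is synthesised on exactly the in-band rFFT bins with
independent Gaussian sine/cosine coefficients (random phases), giving
exact band control. After spatial smoothing of the signal component, each
voxel series is rescaled to its target sample standard deviation, so the
planted amplitude is exact, sharp at the ROI boundary, and unbiased by
smoothing-induced variance loss. The per-subject amplitude jitter
(lognormal-like multiplicative factor, CV 0.10) supplies the
between-subject variance a real cohort has; without it the group contrast
would only face within-subject estimation noise. Positivity holds by
construction (baseline ≥ 10·(amplitude+noise)); if a draw still crosses
zero the volume is shifted up and the shift recorded in the image
metadata — clipping is avoided because it would bias μ.

Per-subject seeds derive from the master seed through a seeded generator,
so cohorts are bit-reproducible and subjects independent. The expected
patient/control PerAF ratio inside an effect ROI is
√((f²a² + s²)/(a² + s²)) for effect factor f, fluctuation σ a and noise σ
s — 0.63 at the defaults.

What the generator does **not** model: hemodynamic responses or task
structure, cardiac/respiratory noise, EPI distortion, image-corrupting
motion (motion exists only as a realignment-parameter trace feeding the
exclusion rule), tissue contrast (the nuisance "white-matter" and
"ventricle" ROIs in synthetic runs are stand-in corner spheres), and
spatial non-stationarity. Passing recovery tests therefore show that the
pipeline's statistics behave correctly under a controlled amplitude
model, not that the preprocessing would suffice on scanner data.

## Problem sizes used in tests and the acceptance script

The family-wise-error calibration uses a 20³ mask, 2-voxel FWHM, 1,000
Monte-Carlo iterations and 500 null cohorts of 10+10 maps. Planted-effect
recovery runs 20 replicate cohorts at the full default conditions
(18+18 subjects, 24³×245), with the 1,000-shuffle permutation test on one
replicate. The permutation-validity check uses 200 null feature tables of
12 subjects at 99 shuffles. These sizes were chosen to keep every
statistical check at meaningful resolution on a single CPU.

## Known limitations

* The Monte-Carlo null assumes stationary Gaussian smoothness set by the
  map-smoothing FWHM; no residual-based smoothness estimation.
* DeLong CIs are asymptotic; at n = 18+18 with near-perfect separation
  they touch the [0, 1] truncation.
* The LOO-SVM with two highly correlated regional features is close to a
  univariate classifier; no feature selection or kernel search is done.
* No covariate adjustment (ANCOVA) in the voxelwise model; group
  comparability is reported descriptively in the cohort table instead.
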