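# Methods

## Problem and data model

Patients with locally advanced rectal cancer receive neoadjuvant
chemotherapy; pathology of the resected specimen grades regression
(pTRG 0–3), and pTRG 3 defines the *nonresponse* class.  Imaging
consists of one pre-treatment and one post-treatment 2D ADC map per
patient (units 10⁻³ mm²/s) with a manually delineated single-slice
tumor ROI.  The package predicts the binary nonresponse label from
first-order statistics of the masked ADC histogram, and compares that
texture model against (a) a logistic model on manually measured mean
ADC values and (b) simulated subjective radiologist calls.

## Feature definitions and conventions

For the ROI values, population (biased) central moments are used
throughout; at ROI sizes of ~10³ pixels the sample-size corrections are
far below measurement noise, and biased moments are the common default
in image-texture toolchains.

- **Units.** Means and manual ADC values are reported in 10⁻³ mm²/s.
  SD is reported in 10⁻⁵ mm²/s (raw SD × 100) and variance as the
  square of the reported SD.  This reconciles the scales on which the
  reference cohort's summaries are printed (means ≈ 1, SDs ≈ 12,
  variances ≈ 150 with variance ≈ SD²) and is logged as an explicit
  convention.
- **Entropy.** `E = Σ pᵢ log₂ pᵢ` over a 256-bin histogram of the ROI
  values min–max scaled to [0, 255]; empty bins contribute 0, a
  zero-width range yields E = 0, and the value lies in [−8, 0].  The
  signed (negative-Shannon) convention matches the scale of the
  reference cohort, whose printed entropies are ≈ −5 — impossible for
  nonnegative Shannon entropy.  Because the binning is per-ROI min–max,
  entropy (and skewness/kurtosis) are invariant to global intensity
  rescaling; this per-ROI gray-level mapping is also the pipeline's
  normalization step for cross-scanner intensity differences.  A
  whole-image z-score alternative was considered and rejected as the
  default because the per-ROI mapping is what makes the shape features
  scanner-invariant.
- **Kurtosis** is excess kurtosis (normal → 0); the reference cohort's
  printed post-treatment kurtosis of 0.325 is below the theoretical
  minimum of non-excess kurtosis, which fixes this convention.
- **Degenerate ROIs** (zero variance) return 0 for SD, variance, shape
  statistics and entropy with an explicit flag rather than NaN.
- **Manual ADC.** The per-patient ADC is the arithmetic mean of two
  readers' measurements (no single-reader fallback); `ADC_change =
  post_ADC − pre_ADC`, and identically for every `*_change` feature.

## Reproducibility filter

ICC(2,1) — two-way random effects, absolute agreement, single
measurement — is computed per feature from the two readers' feature
tables and features with ICC > 0.75 (strict) are retained.  Absolute
agreement was chosen over consistency because a systematic offset
between readers *should* count against a feature that feeds a fixed
decision rule; a consistency variant is available by option.  Whether
single- or average-measure ICC is the "right" reading of common
practice is genuinely open; single-measure is the conservative choice
since downstream use relies on one delineation.

## Models

**TA model.** A random forest (default 500 trees, unlimited depth,
√p features per split, no class weighting, fixed seed) on texture
features selected by Gini importance (mean decrease in impurity) of a
seeded ranking forest; the top k = 5 features are kept by default,
reproducing a five-feature texture model.  Ties in importance break by
feature name so ranking is deterministic.  Predicted probability is
the soft-vote fraction of trees.  Hyperparameters are deliberately
plain: the forest is not the scientific contribution, its ordering
relative to the ADC model and readers is.

**ADC model.** Candidates are the manual ADC quantities whose
two-group comparison has p < 0.05.  Forward stepwise logistic
regression with likelihood-ratio tests then adds the best candidate
while p < 0.05 and re-tests entered terms for removal at p > 0.10 —
the common statistical-package defaults for forward-LR.  Perfect
separation falls back to a ridge-penalized fit for the affected step
with a logged warning.

**Evaluation.** AUC is the trapezoid over the empirical ROC and equals
the Mann–Whitney U statistic over n₁n₂ (ties ½) bit-exactly.  Single
AUC variance and the paired test use DeLong placement values; CIs are
Wald with the DeLong SE, clipped to [0, 1] (the exact CI method of
commercial ROC software varies; Wald is the transparent choice).  The
Youden operating point breaks ties toward higher specificity.  A
binary rater is a two-point classifier whose AUC is
(sensitivity + specificity)/2.  Cohen's kappa uses the Fleiss
large-sample SE.  Continuous group comparisons select Student's t
(Welch by option) when both groups pass Shapiro–Wilk at α = 0.05, else
Mann–Whitney; categorical tables use χ² without continuity correction
when every expected count exceeds 5 (strictly — borderline tables go
to the exact test), else Fisher's exact (2×2) or Freeman–Halton
enumeration (small 2×k).

One deliberate boundary case: comparing a perfectly separating score
vector (resubstitution AUC = 1, hence zero DeLong variance) against a
weaker model has an undefined DeLong z.  The evaluation primitive
raises on this degenerate input; the pipeline records the comparison
as decisive in the limit (z → ∞, p → 0) with an explicit
`degenerate_variance` flag, since an AUC difference with literally no
sampling variability on the observed data is the strongest evidence
the statistic can express.

## Synthetic cohort generator

No public imaging accompanies the reference cohort, so the generator
defines the study conditions:

1. **Per-patient targets.** Ten quantities are sampled jointly per
   patient — pre-treatment mean, SD, skewness, excess kurtosis, manual
   ADC, and their post-minus-pre changes — from a multivariate normal
   whose per-group means and SDs are the reference cohort's printed
   summaries and whose correlation is exchangeable with ρ = 0.3 by
   default (configurable; the source reports no joint structure, and
   independence would understate the texture model's attainable
   separation).  Post-treatment targets are pre + change, so the
   change features carry the configured group statistics by
   construction; the post-treatment SDs implied by this construction
   differ slightly from the printed post rows, which cannot all be
   matched simultaneously by any single correlation.
2. **Feasibility.** Sampled (skewness, kurtosis) pairs are clamped to
   |skew| ≤ 2.5, kurt ≤ 12 (plausible for tumor-ROI histograms) and
   projected to the nearest point of the region reachable by the cubic
   transform, approximated by kurt ≥ max(s² − 2, 1.641·s² − 1.2264)
   plus a 0.2 safety margin that keeps the *sample-level* boundary of
   a finite ROI reachable.  Projection only ever raises kurtosis, so
   group means of sampled kurtosis targets are biased upward relative
   to the configured means (the printed kurtosis SDs simply imply
   infeasible draws); means of location/scale/ADC features are
   unbiased, and the tests check exactly that split.
3. **Pixel realization.** ROI pixels are `y = a + bz + cz² + dz³` of
   standard normal noise (the classical third-order power method), but
   the coefficients are solved against the *realized sample's* moments
   and the result affinely mapped to the target mean/SD — so the
   extracted empirical moments match the targets to solver precision,
   not merely in expectation (tolerances: 1% relative on mean/SD, 0.1
   absolute on skewness/kurtosis; in practice ~10⁻⁶).  Pixels are
   spatially i.i.d., which is irrelevant to histogram features by
   design.  Non-positive realizations are redrawn (bounded retries)
   and, as a last resort, floor-shifted with the shift recorded in
   metadata.  Entropy is *not* independently targeted: it is an
   emergent property of the realized histogram, and its absolute level
   (≈ −7 for ~1,300-pixel ROIs) depends on ROI size rather than
   matching the reference prints.
4. **Readers.** ROIs are filled ellipses with per-patient random
   geometry; the second reader's mask perturbs the boundary radially
   by a smooth low-order Fourier field of fractional amplitude 0.08 by
   default (guaranteed to differ in ≥ 1 pixel, overlap ≥ 50%).
   Because the perturbed ring includes background pixels, shape
   statistics lose more agreement than location statistics — giving
   the ICC filter real work, as in practice.  Subjective binary calls
   are Bernoulli at configurable per-reader sensitivity/specificity
   (defaults: 0.278/0.956 and 0.306/0.949); an `exact` mode realizes
   the rounded operating counts exactly.  Manual ADC readings are the
   patient's ADC target plus independent N(0, 0.02²) per-reader noise.
5. **Cohorts.** The default study generates a 243-patient center-A
   cohort (45 non-responders), randomly split 194:49 (unstratified by
   default, stratification by flag), plus a 56-patient external cohort
   (33 non-responders) whose pixel values get a global intensity scale
   drawn within ±10%, standing in for different scanner hardware and
   exercising the normalization stage.  Covariates (age, sex, cT, cN)
   are sampled from the reference demographics per group.  Everything
   derives from one seed via spawned generators; identical
   (config, seed) gives bit-identical targets, images and manifests.

### What passing tests do and do not show

The generator reproduces the *marginal group statistics* and a plausible
correlation structure — not rectal anatomy, scanner physics, spatial
texture, lumen/necrosis exclusions, or the true joint distribution of
features.  Consequently, model-comparison results on synthetic cohorts
demonstrate that the pipeline's machinery is correct and that group
separations of the configured size are detectable in the configured
ordering; they do not re-establish the clinical effect sizes, and the
headline validation AUCs of the reference study (0.997/0.919/0.938)
depend on that study's private images and are not reproduced here.
Which texture features the Gini ranking selects on synthetic data also
differs from the reference five, because feature informativeness under
the synthetic joint distribution (and the ICC filter's outcome under
i.i.d. pixels) differs from the real one.

## Problem sizes used

The test suite and acceptance script run the model-dominance sweep at
20 generator seeds on full-size 194-patient primary cohorts with
200-tree forests, moment recovery at 1,000 random targets on a
~2,000-pixel ROI, the DeLong-vs-bootstrap check at 200,000 stratified
m = n−1 resamples of a fixed 12-subject example, and the type-I-error
check at 2,000 null replicates — sizes chosen so the whole suite
completes in a few minutes on one CPU while keeping Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- 2D single-slice ROIs only; no DICOM ingestion; no survival or
  toxicity endpoints; no second-order (GLCM/GLRLM) features.
- The exchangeable-ρ target correlation and the reader-noise scales
  are explicit assumptions, not estimates.
- The stepwise ADC model frequently ends intercept-only on synthetic
  cohorts (the configured manual-ADC group separation is weak at
  n = 36/158, as its borderline printed p-values suggest); this is the
  honest consequence of the configured effect sizes.
- Kappa between simulated readers is an emergent quantity; the joint
  reader table needed to reproduce a specific kappa is not public.
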