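# adct — ADC-map texture analysis for chemotherapy-response prediction

`adct` is a research pipeline for a question in rectal-cancer imaging:
can quantitative texture analysis of apparent diffusion coefficient
(ADC) maps identify patients with locally advanced rectal cancer who do
**not** respond to neoadjuvant chemotherapy — the patients who might
benefit from additional radiation before surgery?  Response is defined
pathologically (tumor regression grade: nonresponse = pTRG 3, response
= pTRG 0–2), and the imaging question is whether pre- and
post-treatment diffusion MRI can predict that label in advance.

The package implements, as a tested reusable library:

- **First-order texture features** of a masked 2D ADC map: mean,
  SD, variance, skewness, excess kurtosis and histogram entropy
  (signed convention `E = Σ pᵢ log₂ pᵢ` over a 256-bin, per-ROI
  min–max-scaled histogram), at both timepoints plus post-minus-pre
  changes, and dual-reader manual mean-ADC measurements.
- **Reproducibility filtering** by the two-way random-effects,
  absolute-agreement, single-measurement intraclass correlation
  ICC(2,1) on dual-reader delineations, keeping features with
  ICC > 0.75.
- **Two predictive models**: a random-forest texture-analysis (TA)
  model on Gini-importance-selected features, and a logistic ADC model
  built by forward stepwise selection with likelihood-ratio tests
  (enter p < 0.05, remove p > 0.10) over the manual ADC quantities.
- **The evaluation stack**: ROC/AUC with DeLong variance and paired
  DeLong tests, Youden operating points, binary-rater ROC for
  subjective mrTRG-style calls, Cohen's kappa, and the
  t-test/Mann–Whitney and χ²/exact-test rules for group comparisons.
- **A synthetic cohort generator** that disaggregates published
  group-level feature statistics into correlated per-patient moment
  targets and realizes them as pixel data by cubic-polynomial moment
  matching — so the whole pipeline runs end-to-end with no data
  download, including dual-reader masks, simulated subjective readers,
  a random primary/internal split and a scanner-perturbed external
  cohort.

Key statistics, in the field's standard notation: for ROI pixel values
$x_1,\dots,x_n$ with central moments $m_k$, skewness $= m_3/m_2^{3/2}$,
excess kurtosis $= m_4/m_2^2 - 3$; AUC equals the Mann–Whitney
statistic $U/(n_1 n_2)$ with ties counted ½, and the paired DeLong test
uses $z = (\hat A_1 - \hat A_2)/\sqrt{V_1 + V_2 - 2C}$ from placement
-value variances; ICC(2,1) $= (MS_R - MS_E) / (MS_R + MS_E +
\tfrac{2}{n}(MS_C - MS_E))$.

## Worked example

`examples/full_study.py` runs the complete three-cohort study on
synthetic data (simulate → extract → ICC filter → models → evaluation):

```
selected texture features: ['post_entropy', 'entropy_change', 'pre_entropy', 'pre_kurtosis', 'mean_change']
ADC model terms: []

cohort                      n   TA AUC  ADC AUC
primary                   194    1.000    0.500
internal_validation        49    0.714    0.500
external_validation        56    0.727    0.500

primary out-of-fold TA AUC: 0.715
reader 1 AUC 0.615, reader 2 AUC 0.624, kappa 0.125
```

Reading this: on the primary cohort the random-forest texture model
separates non-responders from responders perfectly at resubstitution
(an optimistic estimate — the out-of-fold and validation AUCs near 0.72
are the honest ones), while the stepwise ADC model found no manual-ADC
quantity significant in this draw (an intercept-only model scores
AUC 0.5) and the simulated subjective readers sit near 0.62 with poor
inter-reader agreement (κ ≈ 0.13).  The ordering — texture model above
both the ADC model and subjective reading — is the study's central
claim, and it reproduces on the synthetic cohorts.

Other examples, one per capability: `simulate_cohort.py`,
`extract_features.py`, `reader_agreement.py`,
`fit_and_compare_models.py`.  A thin CLI wraps the same functions:

```sh
adct simulate --out cohort/ --seed 1
adct extract --cohort cohort/ --out features.csv
adct run --out results/ --seed 1
```

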