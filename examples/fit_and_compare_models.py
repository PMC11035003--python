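"""Fit the texture-analysis (random forest) and ADC (stepwise logistic)
models on a synthetic primary cohort and compare their ROC performance
with the DeLong test.
"""

from adct import (
    SyntheticCohortConfig,
    fit_ta_model,
    forward_lr_logistic,
    generate_cohort,
    rank_features_gini,
    roc_auc,
    select_significant_adc_candidates,
)
from adct.pipeline import extract_features, safe_delong

cohort = generate_cohort(SyntheticCohortConfig(seed=6))
table = extract_features(cohort)
labels = table["label"]

ranked = rank_features_gini(
    table, labels,
    feature_names=[c for c in table.columns if c != "label"],
    n_trees=200, seed=6)
print("top-5 features by Gini importance:", ranked.selected)

ta = fit_ta_model(table, labels, feature_names=ranked.selected,
                  n_trees=200, seed=6)
ta_scores = ta.predict_proba(table)

candidates = select_significant_adc_candidates(table)
print("screened ADC candidates (p < 0.05):", candidates)
adc = forward_lr_logistic(table, labels, candidates)
print("terms entering the stepwise ADC model:", adc.entered)
adc_scores = adc.predict_proba(table)

ta_roc = roc_auc(ta_scores, labels)
adc_roc = roc_auc(adc_scores, labels)
cmp = safe_delong(ta_scores, adc_scores, labels)
print(f"\nTA model  resubstitution AUC = {ta_roc.auc:.3f} "
      f"(95% CI {ta_roc.ci[0]:.3f}-{ta_roc.ci[1]:.3f})")
print(f"ADC model resubstitution AUC = {adc_roc.auc:.3f}")
print(f"DeLong comparison p = {cmp['p']:.2e}")

print("\nThe multi-feature texture model separates the groups far better "
      "than the single manual-ADC model on the same patients; resubstitution "
      "AUCs are optimistic, so validate on held-out cohorts (see "
      "run_pipeline for the full three-cohort study).")
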