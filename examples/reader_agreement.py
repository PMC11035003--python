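"""Inter-reader reproducibility (ICC) of texture features and agreement
(Cohen's kappa) of subjective response calls.

Texture features are measured twice per patient, from two readers'
slightly different ROI delineations; features with ICC(2,1) > 0.75 are
considered reproducible.  Subjective binary response calls at realistic
sensitivity/specificity illustrate why visual grading alone is weak.
"""

import numpy as np

from adct import (
    SyntheticCohortConfig,
    binary_rater_roc,
    cohens_kappa,
    generate_cohort,
    icc_report,
    simulate_reader_calls,
)
from adct.pipeline import extract_features

cohort = generate_cohort(SyntheticCohortConfig(
    n_nonresponse=15, n_response=30, seed=2))
t1 = extract_features(cohort, "reader1")
t2 = extract_features(cohort, "reader2")

rep = icc_report(t1, t2, feature_names=[
    "pre_mean", "post_mean", "mean_change", "post_SD", "post_skewness",
    "post_entropy"])
print("feature            ICC   keep")
for _, row in rep.table.iterrows():
    print(f"{row.feature:16s} {row.icc:6.3f}  {'yes' if row.keep else 'no'}")

# subjective calls on a full-size primary cohort (no pixel data needed)
labels = np.repeat(["nonresponse", "response"], [36, 158])
calls1 = simulate_reader_calls(labels, 0.278, 0.956, seed=1)
calls2 = simulate_reader_calls(labels, 0.306, 0.949, seed=2)
kap = cohens_kappa(calls1, calls2)
print(f"\nreader agreement: kappa = {kap.kappa:.3f} "
      f"(95% CI {kap.ci[0]:.3f} to {kap.ci[1]:.3f})")
for name, calls in [("reader 1", calls1), ("reader 2", calls2)]:
    r = binary_rater_roc(calls, labels)
    print(f"{name}: AUC = {r.auc:.3f}")

print("\nMean-based features reproduce almost perfectly across readers "
      "(ICC near 1); shape statistics are more sensitive to the ROI "
      "boundary.  Low kappa shows the two readers' subjective calls "
      "agree little beyond chance.")
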