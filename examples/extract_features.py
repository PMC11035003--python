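"""Extract first-order texture features from a synthetic cohort and
compare them between response groups, as in a clinical feature table.

Each patient contributes 18 histogram statistics of the tumor ROI at
two timepoints (plus changes) and 3 manual dual-reader ADC values.
"""

from adct import SyntheticCohortConfig, compare_groups_numeric, generate_cohort
from adct.pipeline import extract_features

cohort = generate_cohort(SyntheticCohortConfig(
    n_nonresponse=20, n_response=40, seed=4))
table = extract_features(cohort)

print(f"feature table: {table.shape[0]} patients x "
      f"{table.shape[1] - 1} features")
print("\nfeature          nonresp.mean  resp.mean      test        p")
for feature in ["post_mean", "mean_change", "post_SD", "post_entropy",
                "post_ADC", "ADC_change"]:
    res = compare_groups_numeric(table[feature].to_numpy(), table["label"])
    nr = table.loc[table.label == "nonresponse", feature].mean()
    r = table.loc[table.label == "response", feature].mean()
    print(f"{feature:18s} {nr:10.3f} {r:10.3f}  {res.test:>14s}  {res.p:.3f}")

print("\nNon-responders show lower post-treatment mean ADC (restricted "
      "diffusion persists) and a negative mean change; a small p marks a "
      "group difference at the 0.05 level.")
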