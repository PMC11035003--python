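"""Reference cohort statistics used as default simulation targets.

These are the published group-level summaries (mean, SD) of manually
measured ADC values and first-order texture features in a two-center
locally advanced rectal cancer cohort treated with neoadjuvant
chemotherapy (mFOLFOX6, no radiation).  Patients are grouped by
pathological tumor regression grade: ``nonresponse`` (pTRG 3) versus
``response`` (pTRG 0-2).

Units follow the reporting convention of the source cohort:

* ``*_mean``, ``*_ADC`` — 10^-3 mm^2/s
* ``*_SD`` — 10^-5 mm^2/s (i.e. raw SD in 10^-3 units times 100)
* ``*_variance`` — (10^-5 mm^2/s)^2
* skewness / kurtosis — unitless (kurtosis is excess kurtosis)
* entropy — signed sum(p * log2 p) over a 256-bin ROI histogram (<= 0)

Only the pre-treatment and change rows are independent simulation
targets; post-treatment statistics follow as ``post = pre + change``.
Variance and entropy are emergent (variance = SD^2 per patient; entropy
is a property of the realized histogram).
"""

from __future__ import annotations

# (mean, SD) per feature, per pTRG group.  Keys are the canonical
# feature names used throughout the package.
GROUP_FEATURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "nonresponse": {
        "pre_ADC": (0.961, 0.229),
        "post_ADC": (0.947, 0.283),
        "ADC_change": (-0.014, 0.220),
        "pre_mean": (0.962, 0.229),
        "post_mean": (0.906, 0.269),
        "mean_change": (-0.056, 0.125),
        "pre_variance": (150.680, 52.904),
        "post_variance": (169.219, 55.712),
        "variance_change": (18.540, 57.628),
        "pre_skewness": (0.946, 0.715),
        "post_skewness": (0.405, 0.873),
        "skewness_change": (-0.541, 1.238),
        "pre_kurtosis": (1.685, 2.922),
        "post_kurtosis": (1.133, 3.212),
        "kurtosis_change": (-0.552, 3.741),
        "pre_entropy": (-5.108, 0.302),
        "post_entropy": (-5.054, 0.273),
        "entropy_change": (0.054, 0.392),
        "pre_SD": (12.081, 2.208),
        "post_SD": (12.813, 2.277),
        "SD_change": (0.733, 2.494),
    },
    "response": {
        "pre_ADC": (1.018, 0.236),
        "post_ADC": (1.043, 0.256),
        "ADC_change": (0.025, 0.190),
        "pre_mean": (1.030, 0.221),
        "post_mean": (1.060, 0.240),
        "mean_change": (0.030, 0.177),
        "pre_variance": (162.902, 58.214),
        "post_variance": (201.836, 73.256),
        "variance_change": (38.934, 80.590),
        "pre_skewness": (0.811, 0.687),
        "post_skewness": (0.293, 0.690),
        "skewness_change": (-0.518, 0.913),
        "pre_kurtosis": (1.104, 2.117),
        "post_kurtosis": (0.325, 1.233),
        "kurtosis_change": (-0.779, 2.229),
        "pre_entropy": (-5.071, 0.309),
        "post_entropy": (-4.828, 0.463),
        "entropy_change": (0.244, 0.529),
        "pre_SD": (12.560, 2.279),
        "post_SD": (14.000, 2.425),
        "SD_change": (1.440, 2.821),
    },
}

# Features that the synthetic cohort generator samples directly per
# patient.  ``post_*`` statistics are derived as pre + change; variance
# and entropy are emergent properties of the realized pixel data.
TARGETED_FEATURES: tuple[str, ...] = (
    "pre_mean",
    "mean_change",
    "pre_SD",
    "SD_change",
    "pre_skewness",
    "skewness_change",
    "pre_kurtosis",
    "kurtosis_change",
    "pre_ADC",
    "ADC_change",
)

# All 21 quantitative columns of the per-patient feature table.
FEATURE_NAMES: tuple[str, ...] = (
    "pre_mean", "post_mean", "mean_change",
    "pre_SD", "post_SD", "SD_change",
    "pre_variance", "post_variance", "variance_change",
    "pre_skewness", "post_skewness", "skewness_change",
    "pre_kurtosis", "post_kurtosis", "kurtosis_change",
    "pre_entropy", "post_entropy", "entropy_change",
    "pre_ADC", "post_ADC", "ADC_change",
)

# The 18 texture columns (feature table minus the manual ADC values).
TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f for f in FEATURE_NAMES if "ADC" not in f
)

# Cohort composition of the reference study.
COHORT_SIZES: dict[str, dict[str, int]] = {
    "primary": {"nonresponse": 36, "response": 158},
    "internal_validation": {"nonresponse": 9, "response": 40},
    "external_validation": {"nonresponse": 33, "response": 23},
}

# Subjective mrTRG readers' operating points in the primary cohort
# (sensitivity, specificity for calling nonresponse).
READER_OPERATING_POINTS: dict[str, tuple[float, float]] = {
    "reader1": (0.278, 0.956),
    "reader2": (0.306, 0.949),
}

# Demographics of the primary cohort by response group, used to sample
# covariates for synthetic patients.  Age as (mean, SD) years; sex as
# P(male); cT and cN as category probabilities.
COVARIATE_DISTRIBUTIONS: dict[str, dict] = {
    "nonresponse": {
        "age": (49.42, 14.20),
        "p_male": 28 / 36,
        "cT": {"T2": 3 / 36, "T3": 29 / 36, "T4": 4 / 36},
        "cN": {"N0": 4 / 36, "N1": 18 / 36, "N2": 14 / 36},
    },
    "response": {
        "age": (54.22, 11.95),
        "p_male": 110 / 158,
        "cT": {"T2": 12 / 158, "T3": 114 / 158, "T4": 32 / 158},
        "cN": {"N0": 43 / 158, "N1": 58 / 158, "N2": 57 / 158},
    },
}
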