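"""Inter-reader reproducibility of texture features via the intraclass
correlation coefficient.

Features are measured twice per patient, once from each reader's ROI
delineation.  Agreement is quantified with the two-way random-effects,
absolute-agreement, single-measurement ICC — ICC(2,1) in the
Shrout-Fleiss taxonomy — computed from the two-way ANOVA mean squares:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

with n subjects, k = 2 raters, MS_R the between-subject, MS_C the
between-rater and MS_E the residual mean square.  Absolute agreement
(rather than consistency) penalizes a systematic offset between
readers, which is the relevant notion when a feature's value feeds a
fixed decision rule.  A consistency variant is available by option.

Features with ICC > 0.75 (strict) are considered reproducible and
retained for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ICC_THRESHOLD = 0.75


@dataclass
class ICCEstimate:
    icc: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    form: str  # "absolute" or "consistency"


@dataclass
class ICCReport:
    """Per-feature ICC estimates with the keep decision at a threshold."""

    table: pd.DataFrame  # columns: feature, icc, keep
    threshold: float = ICC_THRESHOLD

    def kept_features(self) -> list[str]:
        return self.table.loc[self.table["keep"], "feature"].tolist()


def _anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    n, k = ratings.shape
    grand = ratings.mean()
    subj_means = ratings.mean(axis=1)
    rater_means = ratings.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    ms_subj = ss_subj / (n - 1)
    ms_rater = ss_rater / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(ms_subj), float(ms_rater), float(ms_err)


def icc_absolute_single(ratings, form: str = "absolute") -> ICCEstimate:
    """ICC for a subjects x 2-raters matrix of measurements.

    ``form="absolute"`` gives ICC(2,1) (two-way random effects, absolute
    agreement, single measurement); ``form="consistency"`` gives the
    consistency ICC(3,1) which ignores the rater mean square.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must be a subjects x 2 matrix")
    n = ratings.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(ratings)):
        raise ValueError("missing or non-finite ratings")
    if np.ptp(ratings) == 0:
        raise ValueError("degenerate ratings: zero total variance")

    ms_subj, ms_rater, ms_err = _anova_mean_squares(ratings)
    k = 2
    if form == "absolute":
        denom = ms_subj + (k - 1) * ms_err + (k / n) * (ms_rater - ms_err)
    elif form == "consistency":
        denom = ms_subj + (k - 1) * ms_err
    else:
        raise ValueError(f"unknown ICC form: {form!r}")
    if denom == 0:
        raise ValueError("degenerate ratings: zero denominator")
    icc = (ms_subj - ms_err) / denom
    return ICCEstimate(float(icc), ms_subj, ms_rater, ms_err, form)


def icc_report(
    features_reader1: pd.DataFrame,
    features_reader2: pd.DataFrame,
    feature_names: list[str] | None = None,
    threshold: float = ICC_THRESHOLD,
    form: str = "absolute",
) -> ICCReport:
    """Per-feature ICC from two readers' feature tables (rows aligned by
    index = patient)."""
    if feature_names is None:
        feature_names = [
            c for c in features_reader1.columns if c in features_reader2.columns
            and pd.api.types.is_numeric_dtype(features_reader1[c])
        ]
    rows = []
    for name in feature_names:
        ratings = np.column_stack(
            [features_reader1[name].to_numpy(), features_reader2[name].to_numpy()]
        )
        est = icc_absolute_single(ratings, form=form)
        rows.append({
            "feature": name,
            "icc": est.icc,
            "ms_subjects": est.ms_subjects,
            "ms_raters": est.ms_raters,
            "ms_error": est.ms_error,
            "keep": est.icc > threshold,
        })
    return ICCReport(pd.DataFrame(rows), threshold=threshold)


def filter_features(report: ICCReport, threshold: float | None = None) -> list[str]:
    """Names of features whose ICC strictly exceeds the threshold,
    in the report's order."""
    thr = report.threshold if threshold is None else threshold
    return report.table.loc[report.table["icc"] > thr, "feature"].tolist()
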