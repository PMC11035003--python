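"""Statistical comparison stack: ROC/AUC with DeLong variance and paired
tests, binary-rater ROC, Cohen's kappa, and two-group comparisons.

AUC is computed by the trapezoid over the empirical ROC curve, which is
identical to the Mann-Whitney U statistic divided by n1*n2 with ties
counted 1/2.  The variance of a single AUC and the covariance of two
paired AUCs use DeLong's structural components (placement values); the
paired test statistic is

    z = (AUC_A - AUC_B) / sqrt(V_A + V_B - 2 Cov)

with a two-sided normal p-value.  Confidence intervals for AUC are Wald
intervals with the DeLong SE, clipped to [0, 1].

The two-group comparison for continuous features mirrors the common
clinical-reporting rule: Shapiro-Wilk normality at alpha = 0.05 in each
group selects Student's t-test (Welch by option), otherwise the
Mann-Whitney U test.  Categorical tables use the chi-square test
without continuity correction when all expected counts are >= 5, else
an exact test (hypergeometric for 2x2, Freeman-Halton enumeration for
small 2xk tables).  The chi-square condition is strict (every expected
count must exceed 5), so borderline tables fall through to the exact
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

POSITIVE_LABEL = "nonresponse"


# --------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    variance: float          # DeLong variance of the AUC
    ci: tuple[float, float]  # Wald 95% CI, clipped to [0, 1]
    youden_sensitivity: float
    youden_specificity: float
    youden_threshold: float


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    difference: float
    covariance: float
    z: float
    p: float


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    observed_agreement: float
    chance_agreement: float


def _as_binary_labels(labels) -> np.ndarray:
    """Map labels to {0, 1} with 1 = positive class (nonresponse)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE_LABEL).astype(int)
    return (arr != 0).astype(int)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    # psi(x, y) = 1 if x > y, 1/2 if x == y, 0 if x < y
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = _as_binary_labels(labels)
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC curve with DeLong variance and Youden operating point.

    Higher scores indicate the positive (nonresponse) class.  The
    Youden point maximizes sensitivity + specificity - 1; ties are
    broken toward higher specificity.
    """
    pos, neg = _split_scores(scores, labels)
    scores = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    n1, n0 = pos.size, neg.size

    # curve over all unique score thresholds (predict positive if >= t)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])

    v10, v01 = _placements(pos, neg)
    # summing psi over all pairs before dividing keeps the AUC bit-exact
    # with the Mann-Whitney U statistic divided by n1*n0
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.sum() / (n1 * n0))
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    variance = s10 / n1 + s01 / n0
    se = math.sqrt(max(variance, 0.0))
    ci = (max(0.0, auc - 1.959963984540054 * se),
          min(1.0, auc + 1.959963984540054 * se))

    youden = tpr - fpr
    # argmax with ties broken toward higher specificity (lower fpr);
    # thresholds are in decreasing-sensitivity order so scan for the
    # best (youden, -fpr) pair
    best = max(range(len(thresholds)), key=lambda i: (youden[i], -fpr[i]))
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        variance=variance,
        ci=ci,
        youden_sensitivity=float(tpr[best]),
        youden_specificity=float(1.0 - fpr[best]),
        youden_threshold=float(thresholds[best]),
    )


def binary_rater_roc(calls, labels) -> ROCResult:
    """ROC of a binary rater: a two-point classifier whose AUC equals
    (sensitivity + specificity) / 2 via the trapezoid through its single
    interior operating point."""
    calls = np.asarray(_as_binary_labels(calls), dtype=float)
    return roc_auc(calls, labels)


def delong_paired_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    pos_a, neg_a = _split_scores(scores_a, labels)
    pos_b, neg_b = _split_scores(scores_b, labels)
    n1, n0 = pos_a.size, neg_a.size

    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    def cov(u, v):
        if u.size < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    var_a = cov(v10a, v10a) / n1 + cov(v01a, v01a) / n0
    var_b = cov(v10b, v10b) / n1 + cov(v01b, v01b) / n0
    cov_ab = cov(v10a, v10b) / n1 + cov(v01a, v01b) / n0
    var_diff = var_a + var_b - 2.0 * cov_ab
    diff = auc_a - auc_b

    if var_diff <= 0.0:
        if abs(diff) < 1e-12:
            return DeLongComparison(auc_a, auc_b, 0.0, cov_ab, 0.0, 1.0)
        raise ValueError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    z = diff / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_a, auc_b, diff, cov_ab, float(z), float(p))


# --------------------------------------------------------------------------
# Inter-rater agreement


def cohens_kappa(calls_a, calls_b) -> KappaResult:
    """Cohen's kappa for two raters' binary calls, with the Fleiss
    large-sample standard error and a Wald 95% CI."""
    a = _as_binary_labels(calls_a)
    b = _as_binary_labels(calls_b)
    if a.shape != b.shape:
        raise ValueError("raters must rate the same subjects")
    n = a.size
    cats = (0, 1)
    table = np.array([[np.sum((a == i) & (b == j)) for j in cats] for i in cats],
                     dtype=float)
    p = table / n
    po = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        raise ValueError("kappa undefined: both raters constant and equal")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance
    t1 = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
        for i in range(2)
    )
    t2 = sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j
    )
    t2 *= (1.0 - kappa) ** 2
    t3 = (kappa - pe * (1.0 - kappa)) ** 2
    var = (t1 + t2 - t3) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    ci = (kappa - 1.959963984540054 * se, min(1.0, kappa + 1.959963984540054 * se))
    return KappaResult(float(kappa), se, ci, po, pe)


# --------------------------------------------------------------------------
# Two-group comparisons


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float


def compare_groups_numeric(
    values, labels, alpha_normality: float = 0.05, welch: bool = False
) -> GroupComparison:
    """Two-sided comparison of a continuous feature between the two
    response groups.

    Shapiro-Wilk normality at ``alpha_normality`` in each group selects
    Student's t-test (Welch variant if ``welch``); otherwise the
    Mann-Whitney U test with tie correction.
    """
    values = np.asarray(values, dtype=float)
    y = _as_binary_labels(labels)
    g1, g0 = values[y == 1], values[y == 0]
    if g1.size < 2 or g0.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.ptp(g1) == 0 and np.ptp(g0) == 0:
        raise ValueError("constant values in both groups")

    def normal(g):
        if np.ptp(g) == 0 or g.size < 3:
            return False
        return stats.shapiro(g).pvalue > alpha_normality

    if normal(g1) and normal(g0):
        res = stats.ttest_ind(g1, g0, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
        return GroupComparison(name, float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
    return GroupComparison("mann_whitney_u", float(res.statistic), float(res.pvalue))


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> GroupComparison:
    """Pooled two-sample t-test from group summary statistics only."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2)
    return GroupComparison("student_t", float(res.statistic), float(res.pvalue))


def _freeman_halton_2xk(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2xk table by full enumeration of
    tables with the observed margins (multivariate hypergeometric)."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    r0 = int(row[0])

    def log_fact(m):
        return math.lgamma(m + 1)

    log_denom = (
        sum(log_fact(c) for c in col) + sum(log_fact(r) for r in row)
        - log_fact(n)
    )

    def table_logp(first_row):
        lp = -sum(
            log_fact(a) + log_fact(c - a) for a, c in zip(first_row, col)
        )
        return log_denom + lp

    obs_lp = table_logp(table[0])
    ranges = [range(0, int(c) + 1) for c in col[:-1]]
    p = 0.0
    for combo in product(*ranges):
        last = r0 - sum(combo)
        if last < 0 or last > col[-1]:
            continue
        lp = table_logp(list(combo) + [last])
        if lp <= obs_lp + 1e-9:
            p += math.exp(lp)
    return min(1.0, p)


def compare_groups_categorical(table) -> GroupComparison:
    """Chi-square (no continuity correction) when all expected counts are
    >= 5, otherwise an exact conditional test."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk contingency table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("empty row or column")

    expected = stats.contingency.expected_freq(table)
    if np.all(expected > 5):
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("chi_square", float(chi2), float(p))
    if table.shape == (2, 2):
        res = stats.fisher_exact(table.astype(int))
        return GroupComparison("fisher_exact", float(res[0]), float(res[1]))
    p = _freeman_halton_2xk(table)
    return GroupComparison("freeman_halton_exact", float("nan"), p)
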