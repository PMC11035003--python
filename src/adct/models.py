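"""The two predictive models compared by the pipeline.

The texture-analysis (TA) model is a random-forest classifier on a
small set of texture features selected by Gini importance (mean
decrease in node impurity) of a seeded forest.  By default the five
features of the reference model are used: post_mean, mean_change,
post_skewness, post_entropy, entropy_change.

The ADC model is a logistic regression built by forward stepwise
selection with the likelihood-ratio test: candidates are the manual ADC
quantities (pre_ADC, post_ADC, ADC_change) that differ between response
groups at p < 0.05; at each step the candidate with the smallest
LR-test p-value enters if p < p_enter (0.05), and entered terms are
re-tested for removal at p_remove (0.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, optimize
from sklearn.ensemble import RandomForestClassifier

from .evaluation import POSITIVE_LABEL, compare_groups_numeric

DEFAULT_TA_FEATURES = (
    "post_mean", "mean_change", "post_skewness", "post_entropy", "entropy_change",
)

DEFAULT_N_TREES = 500
DEFAULT_K_SELECT = 5

ADC_CANDIDATES = ("pre_ADC", "post_ADC", "ADC_change")


def _binary_outcome(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE_LABEL).astype(int)
    return (arr != 0).astype(int)


# --------------------------------------------------------------------------
# Gini-importance feature ranking


@dataclass
class RankedFeatures:
    """Features ordered by Gini importance; ``selected`` is the top-k."""

    features: list[str]          # in importance order (ties by name)
    importances: dict[str, float]
    k: int

    @property
    def selected(self) -> list[str]:
        return self.features[: self.k]


def rank_features_gini(
    table: pd.DataFrame,
    labels,
    feature_names: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    k: int = DEFAULT_K_SELECT,
    seed: int = 0,
) -> RankedFeatures:
    """Rank features by mean decrease in Gini impurity of a seeded forest.

    Ties in importance are broken by feature-name order so the ranking
    is fully deterministic given (data, seed).
    """
    if feature_names is None:
        feature_names = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
    X = table[feature_names].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("feature table contains missing or non-finite values")
    y = _binary_outcome(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    imp = dict(zip(feature_names, forest.feature_importances_))
    order = sorted(feature_names, key=lambda f: (-imp[f], f))
    return RankedFeatures(order, imp, k=min(k, len(order)))


# --------------------------------------------------------------------------
# TA model (random forest)


@dataclass
class TAModel:
    """Random-forest texture-analysis model; probabilities are soft-vote
    fractions of trees predicting nonresponse."""

    feature_names: list[str]
    n_trees: int = DEFAULT_N_TREES
    max_depth: int | None = None
    class_weight: str | dict | None = None
    seed: int = 0
    forest: RandomForestClassifier | None = field(default=None, repr=False)

    def fit(self, table: pd.DataFrame, labels) -> "TAModel":
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"features absent from table: {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        y = _binary_outcome(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        self.forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            class_weight=self.class_weight,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest.fit(X, y)
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Probability of nonresponse for each row."""
        if self.forest is None:
            raise RuntimeError("model is not fitted")
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"unseen feature names at predict: {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        pos = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, pos]


def fit_ta_model(
    table: pd.DataFrame,
    labels,
    feature_names: list[str] = DEFAULT_TA_FEATURES,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int | None = None,
    class_weight=None,
    seed: int = 0,
) -> TAModel:
    return TAModel(
        list(feature_names), n_trees=n_trees, max_depth=max_depth,
        class_weight=class_weight, seed=seed,
    ).fit(table, labels)


# --------------------------------------------------------------------------
# ADC model (forward-LR stepwise logistic regression)


@dataclass
class StepRecord:
    action: str      # "enter" or "remove"
    term: str
    p: float


@dataclass
class ADCLogisticModel:
    candidates: list[str]
    entered: list[str]
    coefficients: pd.DataFrame  # term, coef, se (includes intercept)
    steps: list[StepRecord]
    p_enter: float
    p_remove: float
    penalized: bool = False

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        coefs = dict(zip(self.coefficients["term"], self.coefficients["coef"]))
        eta = np.full(len(table), coefs.get("intercept", 0.0))
        for term in self.entered:
            eta = eta + coefs[term] * table[term].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """ML logistic fit; returns (params, llf, separated_flag)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            # separation shows up as a saturating likelihood or a failed
            # optimizer, never through coefficient magnitude (which is
            # scale-dependent)
            separated = (not res.mle_retvals.get("converged", False)) or \
                res.llf > -1e-6 or not np.all(np.isfinite(res.bse))
            return np.asarray(res.params), float(res.llf), separated
        except Exception:
            return np.zeros(Xc.shape[1]), -np.inf, True


def _fit_logit_ridge(X: np.ndarray, y: np.ndarray, alpha: float = 1.0):
    """Ridge-penalized logistic fit used when ML fails to converge
    (perfect separation); returns (params, penalized llf)."""
    Xc = sm.add_constant(X, has_constant="add")
    p = Xc.shape[1]

    def negloglik(beta):
        eta = Xc @ beta
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        return -ll + alpha * np.sum(beta[1:] ** 2)

    res = optimize.minimize(negloglik, np.zeros(p), method="BFGS")
    return res.x, -res.fun


def _lr_test_p(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    lr = 2.0 * (llf_full - llf_reduced)
    if lr <= 0:
        return 1.0
    return float(stats.chi2.sf(lr, df))


def forward_lr_logistic(
    table: pd.DataFrame,
    labels,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> ADCLogisticModel:
    """Forward stepwise logistic regression with likelihood-ratio tests.

    At each step the not-yet-entered candidate with the smallest LR-test
    p-value is added if p < p_enter; entered terms are then re-tested
    and removed if their LR p exceeds p_remove.  Selection stops when a
    pass changes nothing.  Perfect separation triggers a
    ridge-penalized fit for the affected step with a warning.
    """
    y = _binary_outcome(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    cols = {c: table[c].to_numpy(dtype=float) for c in candidates}

    entered: list[str] = []
    steps: list[StepRecord] = []
    penalized = False

    def loglik(terms: list[str]) -> float:
        nonlocal penalized
        if not terms:
            # intercept-only log-likelihood, closed form
            p1 = y.mean()
            if p1 in (0.0, 1.0):
                return 0.0
            n = y.size
            return float(n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1)))
        X = np.column_stack([cols[t] for t in terms])
        params, llf, separated = _fit_logit(X, y)
        if separated:
            warnings.warn(
                f"perfect separation fitting {terms}; using ridge penalty",
                RuntimeWarning,
            )
            penalized = True
            _, llf = _fit_logit_ridge(X, y)
        return llf

    changed = True
    while changed:
        changed = False
        # forward step
        remaining = [c for c in candidates if c not in entered]
        if remaining:
            ll_base = loglik(entered)
            best_term, best_p = None, 1.0
            for c in remaining:
                p = _lr_test_p(loglik(entered + [c]), ll_base)
                if p < best_p:
                    best_term, best_p = c, p
            if best_term is not None and best_p < p_enter:
                entered.append(best_term)
                steps.append(StepRecord("enter", best_term, best_p))
                changed = True
        # backward re-test
        if len(entered) > 1:
            ll_full = loglik(entered)
            for c in list(entered):
                p = _lr_test_p(ll_full, loglik([t for t in entered if t != c]))
                if p > p_remove:
                    entered.remove(c)
                    steps.append(StepRecord("remove", c, p))
                    changed = True
                    break

    # final coefficient table
    if entered:
        X = np.column_stack([cols[t] for t in entered])
        params, llf, separated = _fit_logit(X, y)
        if separated:
            params, _ = _fit_logit_ridge(X, y)
            se = np.full(len(params), np.nan)
            penalized = True
        else:
            Xc = sm.add_constant(X, has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params, se = np.asarray(res.params), np.asarray(res.bse)
        terms = ["intercept"] + entered
        coef_df = pd.DataFrame({"term": terms, "coef": params, "se": se})
    else:
        p1 = y.mean()
        icpt = np.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0
        coef_df = pd.DataFrame(
            {"term": ["intercept"], "coef": [icpt],
             "se": [np.sqrt(1.0 / (y.size * p1 * (1 - p1))) if 0 < p1 < 1 else np.nan]}
        )
    return ADCLogisticModel(
        candidates=list(candidates), entered=entered, coefficients=coef_df,
        steps=steps, p_enter=p_enter, p_remove=p_remove, penalized=penalized,
    )


def select_significant_adc_candidates(
    table: pd.DataFrame, labels=None, alpha: float = 0.05,
    candidates: tuple[str, ...] = ADC_CANDIDATES,
) -> list[str]:
    """The manual ADC quantities whose two-group comparison has p < alpha.

    ``labels`` defaults to the table's ``label`` column.  The test for
    each column follows the normality-based t-test / Mann-Whitney rule.
    """
    if labels is None:
        labels = table["label"]
    out = []
    for c in candidates:
        res = compare_groups_numeric(table[c].to_numpy(dtype=float), labels)
        if res.p < alpha:
            out.append(c)
    return out


def filter_significant(pvalues: dict[str, float], alpha: float = 0.05) -> list[str]:
    """Screening rule applied to precomputed per-feature p-values."""
    return [name for name, p in pvalues.items() if p < alpha]
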