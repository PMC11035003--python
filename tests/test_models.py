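"""Gini feature ranking, the random-forest texture model and the
forward-LR stepwise logistic ADC model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adct.evaluation import roc_auc
from adct.models import (
    filter_significant,
    fit_ta_model,
    forward_lr_logistic,
    rank_features_gini,
    select_significant_adc_candidates,
)


def _toy_table(rng, n=200, informative_shift=2.0, n_noise=9):
    y = np.repeat([1, 0], n // 2)
    data = {"signal": rng.normal(informative_shift * y, 1.0)}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.normal(0, 1, n)
    labels = np.where(y == 1, "nonresponse", "response")
    return pd.DataFrame(data), labels


class TestGiniRanking:
    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table, labels = _toy_table(rng)
            ranked = rank_features_gini(table, labels, n_trees=100, seed=seed)
            wins += ranked.features[0] == "signal"
        assert wins >= 48  # >= 95% of runs

    def test_duplicated_feature_shares_importance(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, labels = _toy_table(rng, n_noise=5)
            table["signal_copy"] = table["signal"] + rng.normal(0, 1e-6, len(table))
            ranked = rank_features_gini(table, labels, n_trees=100, seed=seed)
            dup = ranked.importances["signal"] + ranked.importances["signal_copy"]
            top_noise = max(v for k, v in ranked.importances.items()
                            if k.startswith("noise"))
            wins += dup > top_noise
        assert wins >= 19

    def test_null_labels_no_systematically_best_feature(self):
        # under label-independent features, no feature should win the
        # top rank more often than chance (Friedman-type check)
        n_feat, n_rep = 6, 30
        ranks = np.zeros((n_rep, n_feat))
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            table = pd.DataFrame(
                rng.normal(0, 1, (100, n_feat)),
                columns=[f"f{i}" for i in range(n_feat)])
            labels = np.where(rng.random(100) < 0.5, "nonresponse", "response")
            ranked = rank_features_gini(table, labels, n_trees=50, seed=rep)
            for pos, f in enumerate(ranked.features):
                ranks[rep, int(f[1:])] = pos
        stat, p = sps.friedmanchisquare(*ranks.T)
        assert p > 0.01

    def test_importances_sum_to_one(self, small_feature_tables):
        t = small_feature_tables["reader1"]
        ranked = rank_features_gini(
            t, t["label"], feature_names=["pre_mean", "post_mean", "pre_SD"],
            n_trees=50, seed=0)
        assert sum(ranked.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in ranked.importances.values())

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.normal(0, 1, 10)})
        with pytest.raises(ValueError):
            rank_features_gini(table, ["response"] * 10)


class TestTAModel:
    def test_separable_feature_gives_unit_resubstitution_auc(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": np.r_[rng.uniform(2, 3, 20),
                                         rng.uniform(0, 1, 30)]})
        labels = np.array(["nonresponse"] * 20 + ["response"] * 30)
        model = fit_ta_model(table, labels, feature_names=["x"],
                             n_trees=100, seed=0)
        assert roc_auc(model.predict_proba(table), labels).auc == 1.0

    def test_permuted_labels_cv_auc_near_half(self):
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(5)
        table, labels = _toy_table(rng, n=200, informative_shift=2.0)
        labels = rng.permutation(labels)
        y = (labels == "nonresponse").astype(int)
        oof = np.zeros(len(table))
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for tr, te in skf.split(table, y):
            m = fit_ta_model(table.iloc[tr], labels[tr],
                             feature_names=list(table.columns),
                             n_trees=100, seed=0)
            oof[te] = m.predict_proba(table.iloc[te])
        auc = roc_auc(oof, labels).auc
        assert 0.4 <= auc <= 0.6

    def test_seeded_determinism(self, small_feature_tables):
        t = small_feature_tables["reader1"]
        kw = dict(feature_names=["pre_mean", "post_mean"], n_trees=50, seed=9)
        p1 = fit_ta_model(t, t["label"], **kw).predict_proba(t)
        p2 = fit_ta_model(t, t["label"], **kw).predict_proba(t)
        assert np.array_equal(p1, p2)

    def test_probabilities_average_to_prevalence(self, small_feature_tables):
        t = small_feature_tables["reader1"]
        model = fit_ta_model(t, t["label"],
                             feature_names=["post_mean", "mean_change"],
                             n_trees=200, seed=1)
        probs = model.predict_proba(t)
        assert np.all((probs >= 0) & (probs <= 1))
        prevalence = (t["label"] == "nonresponse").mean()
        assert abs(probs.mean() - prevalence) <= 0.05

    def test_unseen_features_at_predict_rejected(self, small_feature_tables):
        t = small_feature_tables["reader1"]
        model = fit_ta_model(t, t["label"], feature_names=["pre_mean"],
                             n_trees=10, seed=0)
        with pytest.raises(ValueError, match="unseen|absent"):
            model.predict_proba(t.drop(columns=["pre_mean"]))


class TestForwardLR:
    def test_constant_candidate_gives_intercept_only(self):
        table = pd.DataFrame({"c": np.ones(40)})
        labels = np.array(["nonresponse"] * 15 + ["response"] * 25)
        model = forward_lr_logistic(table, labels, ["c"])
        assert model.entered == []
        assert model.coefficients["term"].tolist() == ["intercept"]

    def test_only_associated_candidate_enters(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x1, x2 = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
            p = 1 / (1 + np.exp(-(0.2 + 2.0 * x1)))
            y = np.where(rng.random(500) < p, "nonresponse", "response")
            table = pd.DataFrame({"X1": x1, "X2": x2})
            model = forward_lr_logistic(table, y, ["X1", "X2"])
            hits += model.entered == ["X1"]
        assert hits >= 95

    def test_calibrated_post_adc_signal_selects_post_adc(self):
        # two candidates with the signal placed entirely in post_ADC,
        # mirroring a stepwise ADC model where only post_ADC survives
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n1, n0 = 60, 140
            post = np.r_[rng.normal(0.85, 0.25, n1), rng.normal(1.10, 0.25, n0)]
            change = rng.normal(0.0, 0.2, n1 + n0)
            labels = np.array(["nonresponse"] * n1 + ["response"] * n0)
            table = pd.DataFrame({"post_ADC": post, "ADC_change": change})
            model = forward_lr_logistic(table, labels,
                                        ["post_ADC", "ADC_change"])
            hits += model.entered == ["post_ADC"]
        assert hits >= 16

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(17)
        x1 = rng.normal(0, 1, 300)
        x2 = rng.normal(0, 1, 300)
        p = 1 / (1 + np.exp(-(1.5 * x1 - x2)))
        labels = np.where(rng.random(300) < p, "nonresponse", "response")
        t1 = pd.DataFrame({"a": x1, "b": x2})
        t2 = pd.DataFrame({"a": 100 * x1 - 3, "b": 0.01 * x2 + 7})
        m1 = forward_lr_logistic(t1, labels, ["a", "b"])
        m2 = forward_lr_logistic(t2, labels, ["a", "b"])
        assert m1.entered == m2.entered

    def test_perfect_separation_falls_back_to_ridge(self):
        table = pd.DataFrame({"x": np.r_[np.ones(10) * 5, np.zeros(10)]})
        labels = np.array(["nonresponse"] * 10 + ["response"] * 10)
        with pytest.warns(RuntimeWarning, match="separation"):
            model = forward_lr_logistic(table, labels, ["x"])
        assert model.penalized


class TestCandidateScreening:
    def test_null_groups_mostly_empty(self):
        empties = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({
                "pre_ADC": rng.normal(1, 0.2, 100),
                "post_ADC": rng.normal(1, 0.2, 100),
                "ADC_change": rng.normal(0, 0.2, 100),
                "label": ["nonresponse"] * 40 + ["response"] * 60,
            })
            empties += select_significant_adc_candidates(table) == []
        assert empties >= 30  # each feature retained with prob ~alpha

    def test_reference_pvalue_scenario(self):
        pvals = {"pre_ADC": 0.192, "post_ADC": 0.048, "ADC_change": 0.018}
        assert filter_significant(pvals) == ["post_ADC", "ADC_change"]

    def test_strong_separation_selects_all(self):
        rng = np.random.default_rng(4)
        n1, n0 = 100, 100
        table = pd.DataFrame({
            "pre_ADC": np.r_[rng.normal(0, 1, n1), rng.normal(3, 1, n0)],
            "post_ADC": np.r_[rng.normal(0, 1, n1), rng.normal(3, 1, n0)],
            "ADC_change": np.r_[rng.normal(0, 1, n1), rng.normal(3, 1, n0)],
            "label": ["nonresponse"] * n1 + ["response"] * n0,
        })
        assert select_significant_adc_candidates(table) == [
            "pre_ADC", "post_ADC", "ADC_change"]
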