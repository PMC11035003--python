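"""End-to-end orchestration: simulate (or ingest) a cohort, extract
features, filter by inter-reader ICC, fit the texture-analysis and ADC
models, and run the full ROC / DeLong / kappa comparison against
simulated subjective readers.

The default run emulates the reference two-center study: a center-A
cohort randomly split into primary and internal-validation cohorts at
the 194:49 ratio, and an external center-B cohort generated with a
global intensity perturbation standing in for different scanner
hardware.  Feature selection and model fitting only ever see the
primary cohort; validation labels are used exclusively for evaluation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, models, reproducibility
from .features import average_reader_adc
from .reference import COHORT_SIZES, FEATURE_NAMES, TEXTURE_FEATURE_NAMES
from .synthetic import (
    SyntheticCohort,
    SyntheticCohortConfig,
    SyntheticPatient,
    simulate_reader_calls,
)

logger = logging.getLogger("adct")


# --------------------------------------------------------------------------
# Feature extraction


def extract_features(
    cohort: SyntheticCohort, reader: str = "reader1"
) -> pd.DataFrame:
    """Per-patient feature table (21 columns + label) for one cohort.

    ``reader`` selects whose ROI delineation supplies the texture
    features; the manual ADC values are always the two readers'
    averaged measurements.
    """
    rows = []
    for p in cohort.patients:
        pre_mask = p.pre_mask if reader == "reader1" else p.pre_mask_reader2
        post_mask = p.post_mask if reader == "reader1" else p.post_mask_reader2
        fv = features.compute_feature_vector(
            p.pre_map, pre_mask, p.post_map, post_mask)
        row = dict(fv.values)
        pre_adc = average_reader_adc(*p.adc_readings["pre"])
        post_adc = average_reader_adc(*p.adc_readings["post"])
        row["pre_ADC"] = pre_adc
        row["post_ADC"] = post_adc
        row["ADC_change"] = features.adc_change(pre_adc, post_adc)
        row["patient_id"] = p.patient_id
        row["label"] = p.group
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df[list(FEATURE_NAMES) + ["label"]]


def extract_features_from_dir(
    cohort_dir: str | Path, reader: str = "reader1"
) -> pd.DataFrame:
    """Feature table from an on-disk cohort (manifest.csv + images)."""
    from . import imgio

    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    mask_col = {"reader1": "{}_mask", "reader2": "{}_mask_reader2"}[reader]
    rows = []
    for _, r in manifest.iterrows():
        maps, masks = {}, {}
        for tp in ("pre", "post"):
            maps[tp] = imgio.read_adc_map(
                cohort_dir / r[f"{tp}_image"], r["patient_id"], tp)
            masks[tp] = imgio.read_mask(
                cohort_dir / r[mask_col.format(tp)], reader)
        fv = features.compute_feature_vector(
            maps["pre"], masks["pre"], maps["post"], masks["post"])
        row = dict(fv.values)
        pre_adc = average_reader_adc(r["pre_adc_reader1"], r["pre_adc_reader2"])
        post_adc = average_reader_adc(r["post_adc_reader1"], r["post_adc_reader2"])
        row["pre_ADC"] = pre_adc
        row["post_ADC"] = post_adc
        row["ADC_change"] = features.adc_change(pre_adc, post_adc)
        row["patient_id"] = r["patient_id"]
        row["label"] = r["group"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")[
        list(FEATURE_NAMES) + ["label"]]


# --------------------------------------------------------------------------
# Cohort splitting and summaries


def split_cohorts(
    cases: list, fraction: float = 194 / 243, seed: int = 0,
    stratify_labels=None,
) -> tuple[list, list]:
    """Seeded random split of one center's cases into primary and
    internal-validation cohorts at ``fraction`` (default 194:49).

    With ``stratify_labels`` the split is stratified by label;
    otherwise it is a simple random split.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(cases)
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        n_primary = int(round(fraction * n))
        perm = rng.permutation(n)
        take = np.zeros(n, dtype=bool)
        take[perm[:n_primary]] = True
    else:
        labels = np.asarray(stratify_labels)
        take = np.zeros(n, dtype=bool)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            k = int(round(fraction * idx.size))
            take[rng.permutation(idx)[:k]] = True
    primary = [c for c, t in zip(cases, take) if t]
    internal = [c for c, t in zip(cases, take) if not t]
    return primary, internal


def summarize_cohort(manifest: pd.DataFrame) -> dict:
    """Demographics summary by response group: counts and percentages,
    age as mean +/- SD, categorical group comparisons."""
    n = len(manifest)
    groups = manifest["group"]
    summary: dict = {"n": n, "groups": {}}
    for g in ("nonresponse", "response"):
        cnt = int((groups == g).sum())
        summary["groups"][g] = {"n": cnt, "pct": round(100.0 * cnt / n, 1)}
    is_nr = (groups == "nonresponse").to_numpy()
    for col, kind in (("age", "numeric"), ("sex", "categorical"),
                      ("cT", "categorical"), ("cN", "categorical")):
        if col not in manifest.columns or manifest[col].isna().all():
            logger.warning("covariate %r missing; omitted from summary", col)
            continue
        if kind == "numeric":
            vals = manifest[col].to_numpy(dtype=float)
            entry = {
                g: {"mean": float(vals[sel].mean()),
                    "sd": float(vals[sel].std(ddof=1))}
                for g, sel in (("nonresponse", is_nr), ("response", ~is_nr))
            }
            try:
                cmp = evaluation.compare_groups_numeric(vals, groups)
                entry["p"] = cmp.p
                entry["test"] = cmp.test
            except ValueError:
                pass
        else:
            cats = sorted(manifest[col].unique())
            table = np.array([
                [int(((manifest[col] == c) & sel).sum()) for c in cats]
                for sel in (is_nr, ~is_nr)
            ])
            entry = {"categories": cats, "counts": table.tolist()}
            if table.size and not (np.any(table.sum(0) == 0)
                                   or np.any(table.sum(1) == 0)):
                cmp = evaluation.compare_groups_categorical(table)
                entry["p"] = cmp.p
                entry["test"] = cmp.test
        summary[col] = entry
    return summary


# --------------------------------------------------------------------------
# Run configuration


_COHORT_DEFAULTS = {k: dict(v) for k, v in COHORT_SIZES.items()}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Unknown keys are rejected at construction from mappings/YAML.
    """

    seed: int = 0
    out_dir: str | None = None
    cohort_sizes: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _COHORT_DEFAULTS.items()})
    split_center_a: bool = True        # pool center A, then random split
    split_fraction: float = 194 / 243
    stratify_split: bool = False
    correlation: float = 0.3
    roi_shape: tuple[int, int] = (64, 64)
    reader2_mask_jitter: float = 0.08
    reader_adc_noise: float = 0.02
    exact_reader_rates: bool = False   # realize reader sens/spec exactly
    external_scale_magnitude: float = 0.1  # +/- fractional scanner effect
    icc_threshold: float = 0.75
    icc_subset: int | None = None      # re-delineation subsample size
    n_trees: int = 500
    k_select: int = 5
    p_enter: float = 0.05
    p_remove: float = 0.10
    cv_folds: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        for name in ("primary", "internal_validation", "external_validation"):
            sizes = self.cohort_sizes.get(name)
            if not sizes or min(sizes.values()) < 1:
                raise ValueError(f"invalid cohort sizes for {name}")


# --------------------------------------------------------------------------
# Full run


def _cohort_config(cfg: RunConfig, sizes: dict, seed: int) -> SyntheticCohortConfig:
    return SyntheticCohortConfig(
        n_nonresponse=sizes["nonresponse"],
        n_response=sizes["response"],
        correlation=cfg.correlation,
        roi_shape=tuple(cfg.roi_shape),
        reader2_mask_jitter=cfg.reader2_mask_jitter,
        reader_adc_noise=cfg.reader_adc_noise,
        seed=seed,
    )


def _subset_cohort(cohort: SyntheticCohort,
                   patients: list[SyntheticPatient],
                   name: str) -> SyntheticCohort:
    ids = [p.patient_id for p in patients]
    manifest = cohort.manifest.set_index("patient_id").loc[ids].reset_index()
    manifest["cohort"] = name
    return SyntheticCohort(patients=patients, manifest=manifest,
                           config=cohort.config)


def _safe_delong(scores_a, scores_b, labels) -> dict:
    """Paired DeLong comparison, treating a zero-variance difference
    between unequal AUCs (e.g. a perfectly separating model at
    resubstitution) as decisive in the limit (z -> inf, p -> 0)."""
    try:
        return dataclasses.asdict(
            evaluation.delong_paired_test(scores_a, scores_b, labels))
    except ValueError:
        ra = evaluation.roc_auc(np.asarray(scores_a, dtype=float), labels)
        rb = evaluation.roc_auc(np.asarray(scores_b, dtype=float), labels)
        return {
            "auc_a": ra.auc, "auc_b": rb.auc,
            "difference": ra.auc - rb.auc, "covariance": 0.0,
            "z": float("inf") if ra.auc > rb.auc else float("-inf"),
            "p": 0.0, "degenerate_variance": True,
        }


#: public name for the decisive-limit DeLong comparison
safe_delong = _safe_delong


def _roc_entry(result: evaluation.ROCResult) -> dict:
    return {
        "auc": result.auc,
        "ci": list(result.ci),
        "youden_sensitivity": result.youden_sensitivity,
        "youden_specificity": result.youden_specificity,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole study on synthetic data; returns the report.

    Stages: simulate -> extract -> ICC filter -> group comparisons ->
    ADC-candidate screening -> forward-LR ADC model -> Gini ranking ->
    TA model -> ROC / DeLong / kappa on all three cohorts.  Determined
    entirely by (config, seed); with ``config.out_dir`` the report and
    tables are written to disk.
    """
    from .synthetic import generate_cohort

    config.validate()
    rng_root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_root.spawn(6)]
    logger.info("pipeline run with seed=%d; settings=%s", config.seed, config)

    # --- simulate -----------------------------------------------------
    sizes_a = {
        "nonresponse": (config.cohort_sizes["primary"]["nonresponse"]
                        + config.cohort_sizes["internal_validation"]["nonresponse"]),
        "response": (config.cohort_sizes["primary"]["response"]
                     + config.cohort_sizes["internal_validation"]["response"]),
    }
    if config.split_center_a:
        center_a = generate_cohort(
            _cohort_config(config, sizes_a, seeds[0]), cohort_name="center_a")
        strat = center_a.labels if config.stratify_split else None
        prim_pat, int_pat = split_cohorts(
            center_a.patients, config.split_fraction, seed=seeds[1],
            stratify_labels=strat)
        primary = _subset_cohort(center_a, prim_pat, "primary")
        internal = _subset_cohort(center_a, int_pat, "internal_validation")
    else:
        primary = generate_cohort(
            _cohort_config(config, config.cohort_sizes["primary"], seeds[0]),
            cohort_name="primary")
        internal = generate_cohort(
            _cohort_config(config, config.cohort_sizes["internal_validation"],
                           seeds[1]),
            cohort_name="internal_validation")
    ext_rng = np.random.default_rng(seeds[2])
    scale = 1.0 + config.external_scale_magnitude * ext_rng.uniform(-1, 1)
    external = generate_cohort(
        _cohort_config(config, config.cohort_sizes["external_validation"],
                       seeds[2]),
        cohort_name="external_validation",
        intensity_scale=scale,
    )
    cohorts = {"primary": primary, "internal_validation": internal,
               "external_validation": external}

    # --- extract ------------------------------------------------------
    tables = {name: extract_features(c) for name, c in cohorts.items()}
    primary_table = tables["primary"]
    primary_labels = primary_table["label"]

    # --- ICC filter (primary cohort, dual readers) --------------------
    reader2_table = extract_features(primary, reader="reader2")
    if config.icc_subset is not None:
        sub = primary_table.index[:config.icc_subset]
        icc_in1, icc_in2 = primary_table.loc[sub], reader2_table.loc[sub]
    else:
        icc_in1, icc_in2 = primary_table, reader2_table
    icc_rep = reproducibility.icc_report(
        icc_in1, icc_in2, feature_names=list(TEXTURE_FEATURE_NAMES),
        threshold=config.icc_threshold)
    kept = reproducibility.filter_features(icc_rep)
    logger.info("ICC filter kept %d/%d texture features",
                len(kept), len(TEXTURE_FEATURE_NAMES))

    # --- group comparisons (primary) ----------------------------------
    comparisons = {}
    for f in FEATURE_NAMES:
        cmp = evaluation.compare_groups_numeric(
            primary_table[f].to_numpy(), primary_labels)
        comparisons[f] = {"test": cmp.test, "statistic": cmp.statistic,
                          "p": cmp.p}

    # --- ADC model ----------------------------------------------------
    adc_candidates = models.select_significant_adc_candidates(primary_table)
    adc_model = models.forward_lr_logistic(
        primary_table, primary_labels, adc_candidates,
        p_enter=config.p_enter, p_remove=config.p_remove)

    # --- TA model -----------------------------------------------------
    ranked = models.rank_features_gini(
        primary_table, primary_labels, feature_names=kept,
        n_trees=config.n_trees, k=config.k_select, seed=seeds[3])
    ta_model = models.fit_ta_model(
        primary_table, primary_labels, feature_names=ranked.selected,
        n_trees=config.n_trees, seed=seeds[3])

    # --- out-of-fold estimate on the primary cohort -------------------
    from sklearn.model_selection import StratifiedKFold

    y_primary = (primary_labels == "nonresponse").astype(int).to_numpy()
    oof = np.zeros(len(primary_table))
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=seeds[4])
    for tr, te in skf.split(primary_table, y_primary):
        m = models.fit_ta_model(
            primary_table.iloc[tr], primary_labels.iloc[tr],
            feature_names=ranked.selected, n_trees=config.n_trees,
            seed=seeds[4])
        oof[te] = m.predict_proba(primary_table.iloc[te])

    # --- evaluation ---------------------------------------------------
    report: dict = {
        "seed": config.seed,
        "settings": {f.name: getattr(config, f.name)
                     for f in dataclasses.fields(config)
                     if f.name not in ("cohort_sizes", "out_dir")},
        "external_intensity_scale": scale,
        "icc": icc_rep.table[["feature", "icc", "keep"]]
        .to_dict(orient="records"),
        "selected_texture_features": ranked.selected,
        "gini_importances": ranked.importances,
        "adc_candidates": adc_candidates,
        "adc_model_terms": adc_model.entered,
        "group_comparisons": comparisons,
        "cohorts": {},
    }

    reader_rng = np.random.default_rng(seeds[5])
    for name, cohort in cohorts.items():
        table = tables[name]
        labels = table["label"]
        entry: dict = {"summary": summarize_cohort(cohort.manifest)}
        ta_scores = ta_model.predict_proba(table)
        adc_scores = adc_model.predict_proba(table)
        entry["ta_model"] = _roc_entry(evaluation.roc_auc(ta_scores, labels))
        entry["adc_model"] = _roc_entry(evaluation.roc_auc(adc_scores, labels))
        entry["delong_ta_vs_adc"] = _safe_delong(ta_scores, adc_scores, labels)
        if name == "primary":
            entry["ta_model_out_of_fold"] = _roc_entry(
                evaluation.roc_auc(oof, labels))
            calls = {}
            for reader, (sens, spec) in \
                    cohort.config.reader_operating_points.items():
                calls[reader] = simulate_reader_calls(
                    labels.to_numpy(), sens, spec, seed=reader_rng,
                    exact=config.exact_reader_rates)
                rr = evaluation.binary_rater_roc(calls[reader], labels)
                entry[reader] = _roc_entry(rr)
                entry[f"delong_ta_vs_{reader}"] = _safe_delong(
                    ta_scores, calls[reader].astype(float), labels)
            if len(calls) >= 2:
                r1, r2 = list(calls)[:2]
                kap = evaluation.cohens_kappa(calls[r1], calls[r2])
                entry["reader_kappa"] = {
                    "kappa": kap.kappa, "ci": list(kap.ci),
                    "observed_agreement": kap.observed_agreement,
                    "chance_agreement": kap.chance_agreement,
                }
        report["cohorts"][name] = entry

    if config.out_dir is not None:
        _write_report(Path(config.out_dir), report, tables, icc_rep)
    return report


def _write_report(out_dir: Path, report: dict, tables: dict,
                  icc_rep) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=default, sort_keys=True))
    for name, table in tables.items():
        table.to_csv(out_dir / f"features_{name}.csv")
    icc_rep.table.to_csv(out_dir / "icc.csv", index=False)
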