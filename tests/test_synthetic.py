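"""Synthetic cohort generator: target sampling, moment feasibility,
pixel realization round-trips, reader masks and reader calls."""

import numpy as np
import pytest

from adct.features import first_order_stats, masked_pixels
from adct.reference import GROUP_FEATURE_STATS, TARGETED_FEATURES
from adct.synthetic import (
    FEASIBILITY_MARGIN,
    MomentSolverError,
    PatientTargets,
    SyntheticCohortConfig,
    TimepointTargets,
    ellipse_mask,
    generate_cohort,
    jittered_mask,
    min_feasible_kurtosis,
    project_to_feasible,
    sample_feature_targets,
    simulate_reader_calls,
    synthesize_roi_image,
)


def _degenerate_config(**kw):
    targets = {
        g: {f: (GROUP_FEATURE_STATS[g][f][0], 0.0) for f in TARGETED_FEATURES}
        for g in ("nonresponse", "response")
    }
    return SyntheticCohortConfig(feature_targets=targets, **kw)


class TestConfigValidation:
    def test_group_size_floor(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(n_nonresponse=1).validate()

    def test_negative_sd_rejected(self):
        cfg = SyntheticCohortConfig()
        cfg.feature_targets["response"]["pre_mean"] = (1.0, -0.1)
        with pytest.raises(ValueError, match="negative SD"):
            cfg.validate()

    def test_non_psd_correlation_rejected(self):
        p = len(TARGETED_FEATURES)
        mat = np.full((p, p), 0.99)
        np.fill_diagonal(mat, 1.0)
        mat[0, 1] = mat[1, 0] = -0.99  # incompatible with the rest
        with pytest.raises(ValueError, match="positive semi-definite"):
            SyntheticCohortConfig(correlation=mat).validate()

    def test_jitter_range(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(reader2_mask_jitter=0.9).validate()


class TestTargetSampling:
    def test_zero_dispersion_returns_group_means(self):
        cfg = _degenerate_config(n_nonresponse=4, n_response=4, seed=0)
        targets = sample_feature_targets(cfg)
        nr = [t for t in targets if t.group == "nonresponse"]
        stats = GROUP_FEATURE_STATS["nonresponse"]
        for t in nr:
            assert t.pre.mean == pytest.approx(stats["pre_mean"][0])
            assert t.post.mean == pytest.approx(
                stats["pre_mean"][0] + stats["mean_change"][0])
            assert t.pre_adc == pytest.approx(stats["pre_ADC"][0])

    def test_same_seed_identical(self):
        cfg = SyntheticCohortConfig(n_nonresponse=5, n_response=5, seed=42)
        a = sample_feature_targets(cfg)
        b = sample_feature_targets(cfg)
        for ta, tb in zip(a, b):
            assert ta == tb

    def test_post_equals_pre_plus_change_for_mean(self):
        # mean targets are never projected, so the additive construction
        # is exact for them
        cfg = SyntheticCohortConfig(n_nonresponse=50, n_response=50, seed=3)
        for t in sample_feature_targets(cfg):
            assert np.isfinite(t.post.mean)
            assert t.post.sd >= 1.0  # reported-unit floor

    def test_group_mean_recovery_large_sample(self):
        # per-feature sample means should recover the configured group
        # means within 3 standard errors (location/scale/ADC features;
        # skewness and kurtosis are subject to the one-sided feasibility
        # projection, which can only raise kurtosis)
        n = 1000
        cfg = SyntheticCohortConfig(n_nonresponse=n, n_response=2, seed=12)
        targets = [t for t in sample_feature_targets(cfg)
                   if t.group == "nonresponse"]
        stats = GROUP_FEATURE_STATS["nonresponse"]

        def sample_mean(attr):
            return np.mean([getattr(t, attr) if isinstance(attr, str) else attr(t)
                            for t in targets])

        checks = {
            "pre_mean": lambda t: t.pre.mean,
            "mean_change": lambda t: t.post.mean - t.pre.mean,
            "pre_ADC": lambda t: t.pre_adc,
            "ADC_change": lambda t: t.post_adc - t.pre_adc,
            "pre_SD": lambda t: t.pre.sd,
        }
        for feat, getter in checks.items():
            mu, sd = stats[feat]
            got = np.mean([getter(t) for t in targets])
            assert abs(got - mu) <= 3 * sd / np.sqrt(n), feat
        # spec'd post_mean recovery: mean 0.906 by construction
        post_mu = stats["pre_mean"][0] + stats["mean_change"][0]
        got = np.mean([t.post.mean for t in targets])
        assert abs(got - post_mu) <= 3 * 0.240 / np.sqrt(n)
        # kurtosis: projection only ever raises the target
        mu_k, sd_k = stats["pre_kurtosis"]
        got_k = np.mean([t.pre.kurtosis for t in targets])
        assert got_k >= mu_k - 3 * sd_k / np.sqrt(n)


class TestFeasibilityProjection:
    def test_feasible_point_untouched(self):
        assert project_to_feasible(0.5, 1.0) == (0.5, 1.0)

    def test_infeasible_point_lands_on_boundary(self):
        s, k = project_to_feasible(0.0, -3.0)
        assert k == pytest.approx(min_feasible_kurtosis(s), abs=1e-9)

    def test_projection_is_minimal_distance(self):
        # grid-search oracle over the boundary curve
        for s0, k0 in [(0.0, -3.0), (1.5, -1.0), (-2.0, 0.0), (0.8, -2.5)]:
            s, k = project_to_feasible(s0, k0)
            d_proj = np.hypot(s - s0, k - k0)
            grid = np.linspace(s0 - 4, s0 + 4, 20001)
            d_grid = np.min(np.hypot(grid - s0,
                                     [min_feasible_kurtosis(g) - k0
                                      for g in grid]))
            assert d_proj <= d_grid + 1e-6

    def test_bound_dominates_universal_moment_bound(self):
        for s in np.linspace(-3, 3, 31):
            assert min_feasible_kurtosis(s) >= s * s - 2


class TestPixelSynthesis:
    def _targets(self, mean, sd, skew, kurt):
        tp = TimepointTargets(mean, sd, skew, kurt)
        return PatientTargets("PX", "response", tp, tp, mean, mean)

    def test_zero_dispersion_constant_image(self):
        t = self._targets(1.0, 0.0, 0.0, 0.0)
        m, roi, meta = synthesize_roi_image(t, "pre", seed=0)
        vals = masked_pixels(m, roi)
        assert np.all(vals == 1.0)

    def test_gaussian_case_near_zero_skew(self):
        t = self._targets(1.0, 15.0, 0.0, 0.0)
        m, roi, _ = synthesize_roi_image(t, "pre", seed=1)
        s = first_order_stats(masked_pixels(m, roi))
        assert abs(s.skewness) <= 0.1

    def test_reference_group_target_round_trip(self):
        # nonresponse post-treatment group means as one patient's target
        t = self._targets(0.906, 12.8, 0.405, 1.133)
        m, roi, _ = synthesize_roi_image(t, "post", seed=2)
        s = first_order_stats(masked_pixels(m, roi))
        assert s.mean == pytest.approx(0.906, rel=1e-2)
        assert s.sd == pytest.approx(12.8, rel=1e-2)
        assert s.skewness == pytest.approx(0.405, abs=0.1)
        assert s.kurtosis == pytest.approx(1.133, abs=0.1)

    def test_random_feasible_targets_round_trip(self, rng):
        # target ranges emulate plausible tumor-ROI ADC statistics,
        # where the positivity constraint of ADC values is not binding
        for _ in range(25):
            mean = rng.uniform(0.6, 1.4)
            sd = rng.uniform(5.0, min(20.0, 100 * mean / 7))
            skew = rng.uniform(-1.5, 1.5)
            kurt = rng.uniform(min_feasible_kurtosis(skew) + 0.1, 5.0)
            t = self._targets(mean, sd, skew, kurt)
            m, roi, _ = synthesize_roi_image(
                t, "pre", seed=int(rng.integers(2**31)))
            s = first_order_stats(masked_pixels(m, roi))
            assert s.mean == pytest.approx(mean, rel=1e-2)
            assert s.sd == pytest.approx(sd, rel=1e-2)
            assert s.skewness == pytest.approx(skew, abs=0.1)
            assert s.kurtosis == pytest.approx(kurt, abs=0.1)

    def test_pixels_strictly_positive(self, rng):
        t = self._targets(0.7, 18.0, 1.0, 2.0)
        m, roi, meta = synthesize_roi_image(t, "pre", seed=9)
        assert masked_pixels(m, roi).min() > 0

    def test_infeasible_target_raises_named_error(self):
        t = self._targets(1.0, 10.0, 0.0, -2.5)
        with pytest.raises(MomentSolverError, match="mean=1.0"):
            synthesize_roi_image(t, "pre", seed=0)


class TestReaderMasks:
    def test_zero_jitter_identical(self, rng):
        shape = (64, 64)
        center, axes, angle = (32, 32), (20, 14), 0.4
        base = ellipse_mask(shape, center, axes, angle)
        m2 = jittered_mask(shape, center, axes, angle, 0.0, rng)
        assert np.array_equal(base, m2)

    def test_positive_jitter_differs_but_overlaps(self, rng):
        shape = (64, 64)
        center, axes, angle = (32, 32), (20, 14), 0.4
        base = ellipse_mask(shape, center, axes, angle)
        for _ in range(10):
            m2 = jittered_mask(shape, center, axes, angle, 0.08, rng)
            assert not np.array_equal(base, m2)
            overlap = (base & m2).sum()
            assert overlap >= 0.5 * base.sum()
            assert overlap >= 0.5 * m2.sum()


class TestReaderCalls:
    def test_perfect_reader_reproduces_labels(self):
        labels = np.array(["nonresponse"] * 5 + ["response"] * 7)
        calls = simulate_reader_calls(labels, 1.0, 1.0, seed=0)
        assert np.array_equal(calls, (labels == "nonresponse").astype(int))

    def test_blind_reader_all_negative(self):
        labels = np.array(["nonresponse"] * 5 + ["response"] * 7)
        assert simulate_reader_calls(labels, 0.0, 1.0, seed=0).sum() == 0

    def test_sensitivity_matches_binomial_expectation(self):
        labels = np.array(["nonresponse"] * 36 + ["response"] * 158)
        rng = np.random.default_rng(77)
        sens_hat = np.mean([
            simulate_reader_calls(labels, 0.278, 0.956, seed=rng)[:36].mean()
            for _ in range(2000)
        ])
        assert sens_hat == pytest.approx(0.278, abs=0.01)

    def test_exact_mode_realizes_operating_point(self):
        from adct.evaluation import binary_rater_roc

        labels = np.array(["nonresponse"] * 36 + ["response"] * 158)
        calls = simulate_reader_calls(labels, 0.278, 0.956, seed=5, exact=True)
        assert round(binary_rater_roc(calls, labels).auc, 3) == 0.617

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_reader_calls(np.array([0, 1]), 1.2, 0.5)


class TestCohortGeneration:
    def test_reference_primary_cohort_bookkeeping(self, rng):
        cfg = SyntheticCohortConfig(n_nonresponse=36, n_response=158, seed=8)
        cohort = generate_cohort(cfg)
        assert len(cohort.manifest) == 194
        assert (cohort.manifest["group"] == "nonresponse").sum() == 36

    def test_determinism_bit_identical(self):
        cfg = SyntheticCohortConfig(n_nonresponse=3, n_response=3, seed=21)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.manifest.equals(b.manifest)
        for pa, pb in zip(a.patients, b.patients):
            assert np.array_equal(pa.pre_map.pixels, pb.pre_map.pixels)
            assert np.array_equal(pa.post_mask.mask, pb.post_mask.mask)

    def test_reader2_masks_differ_with_jitter(self, small_cohort):
        for p in small_cohort.patients:
            assert not np.array_equal(p.pre_mask.mask,
                                      p.pre_mask_reader2.mask)
            inter = (p.pre_mask.mask & p.pre_mask_reader2.mask).sum()
            assert inter >= 0.5 * p.pre_mask.mask.sum()

    def test_round_trip_through_disk(self, tmp_path):
        from adct.pipeline import extract_features, extract_features_from_dir

        cfg = SyntheticCohortConfig(n_nonresponse=2, n_response=3, seed=33)
        cohort = generate_cohort(cfg, out_dir=tmp_path / "cohort")
        mem = extract_features(cohort)
        disk = extract_features_from_dir(tmp_path / "cohort")
        for col in mem.columns[:-1]:
            assert np.allclose(mem[col], disk[col], rtol=1e-5), col

    def test_png_format_round_trip(self, tmp_path):
        from adct.pipeline import extract_features, extract_features_from_dir

        cfg = SyntheticCohortConfig(n_nonresponse=2, n_response=2, seed=34,
                                    image_format="png")
        cohort = generate_cohort(cfg, out_dir=tmp_path / "cohort")
        mem = extract_features(cohort)
        disk = extract_features_from_dir(tmp_path / "cohort")
        assert np.allclose(mem["pre_mean"], disk["pre_mean"], rtol=1e-3)
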