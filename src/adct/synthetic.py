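"""Synthetic ADC-map cohort generator.

Because no public imaging accession accompanies the reference cohort,
every downstream stage is exercised on synthetic data built in three
layers:

1. **Per-patient feature targets.**  Group-level summary statistics
   (mean, SD per feature and response group; see
   :mod:`adct.reference`) are disaggregated into per-patient targets by
   sampling a correlated multivariate normal over the ten directly
   targeted quantities (pre-treatment mean, SD, skewness, excess
   kurtosis, manual ADC, and their post-minus-pre changes) with an
   exchangeable correlation (default rho = 0.3).  Post-treatment
   targets are constructed as pre + change, so the change statistics
   have the configured group distribution by construction.  Sampled
   (skewness, kurtosis) pairs are projected to the nearest point of the
   moment-feasible region before use.

2. **Pixel realization.**  Each ROI's pixel values are produced by a
   cubic polynomial transform of standard normal noise
   (y = a + b z + c z^2 + d z^3, the classical third-order power
   method) whose coefficients are solved by moment matching so that the
   *empirical* mean, SD, skewness and excess kurtosis of the masked
   pixels hit the patient's targets.  Pixels are spatially i.i.d.: the
   downstream features are purely histogram-based, so spatial
   arrangement is irrelevant.  Entropy is not independently targeted —
   it is an emergent property of the realized histogram.

3. **Readers.**  A second reader's ROI is the first reader's ellipse
   with a smooth random boundary perturbation (for ICC analysis), and
   subjective binary response calls are simulated at configurable
   sensitivity/specificity (for the rater-agreement analysis).
"""

from __future__ import annotations

import math
import shutil
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .features import ADCMap, ROIMask, SD_UNIT_FACTOR
from .reference import (
    COVARIATE_DISTRIBUTIONS,
    GROUP_FEATURE_STATS,
    READER_OPERATING_POINTS,
    TARGETED_FEATURES,
)

GROUPS = ("nonresponse", "response")

#: safety margin (excess-kurtosis units) above the feasibility boundary;
#: wide enough that the *sample* moment boundary of a finite ROI
#: (which fluctuates around the population one) stays reachable
FEASIBILITY_MARGIN = 0.2

#: floor for per-patient SD targets, in reported units (10^-5 mm^2/s)
SD_TARGET_FLOOR = 1.0

#: realism clamps for sampled shape targets: ROI histograms of tumor ADC
#: maps do not plausibly exceed these, and the cubic-transform
#: feasibility approximation degrades beyond them
SKEWNESS_CAP = 2.5
KURTOSIS_CAP = 12.0


class MomentSolverError(RuntimeError):
    """Raised when no pixel realization matches a target moment set."""


# --------------------------------------------------------------------------
# Configuration and per-patient targets


def default_feature_targets() -> dict[str, dict[str, tuple[float, float]]]:
    """Default (mean, SD) targets per group for the ten sampled features."""
    return {
        g: {f: GROUP_FEATURE_STATS[g][f] for f in TARGETED_FEATURES}
        for g in GROUPS
    }


@dataclass
class SyntheticCohortConfig:
    n_nonresponse: int = 36
    n_response: int = 158
    feature_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_feature_targets
    )
    #: exchangeable correlation between targeted features, or a full
    #: symmetric PSD matrix over ``TARGETED_FEATURES``
    correlation: float | np.ndarray = 0.3
    roi_shape: tuple[int, int] = (64, 64)
    #: fractional boundary perturbation of the second reader's ROI
    reader2_mask_jitter: float = 0.08
    #: per-reader (sensitivity, specificity) for simulated mrTRG calls
    reader_operating_points: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(READER_OPERATING_POINTS)
    )
    #: SD of each reader's manual-ADC measurement noise (10^-3 mm^2/s)
    reader_adc_noise: float = 0.02
    image_format: str = "nii"  # "nii" or "png"
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        p = len(TARGETED_FEATURES)
        if np.isscalar(self.correlation):
            rho = float(self.correlation)
            mat = np.full((p, p), rho)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(self.correlation, dtype=float)
        return mat

    def validate(self) -> None:
        if self.n_nonresponse < 2 or self.n_response < 2:
            raise ValueError("each group needs at least 2 patients")
        for g in GROUPS:
            for f, (_, sd) in self.feature_targets[g].items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{f}")
        mat = self.correlation_matrix()
        p = len(TARGETED_FEATURES)
        if mat.shape != (p, p) or not np.allclose(mat, mat.T):
            raise ValueError("correlation must be a symmetric matrix over "
                             "the targeted features")
        if not np.allclose(np.diag(mat), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(mat).min() < -1e-9:
            raise ValueError("correlation matrix is not positive "
                             "semi-definite within tolerance")
        if not (0.0 <= self.reader2_mask_jitter <= 0.5):
            raise ValueError("reader2_mask_jitter must be in [0, 0.5]")
        for r, (sens, spec) in self.reader_operating_points.items():
            if not (0 <= sens <= 1 and 0 <= spec <= 1):
                raise ValueError(f"reader {r}: sens/spec must be in [0, 1]")


@dataclass
class TimepointTargets:
    """Moment targets for one ROI: mean (10^-3 mm^2/s), SD (10^-5
    mm^2/s), skewness and excess kurtosis (unitless)."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float


@dataclass
class PatientTargets:
    patient_id: str
    group: str
    pre: TimepointTargets
    post: TimepointTargets
    pre_adc: float
    post_adc: float


# --------------------------------------------------------------------------
# Moment feasibility


def min_feasible_kurtosis(skewness: float) -> float:
    """Lower edge of the excess-kurtosis region reachable by the cubic
    power-method transform, with a small safety margin.

    The universal moment bound is kurt >= skew^2 - 2; the cubic
    transform's reachable region is slightly narrower, bounded below by
    approximately -1.2264 + 1.6410 skew^2.
    """
    s2 = skewness * skewness
    return max(s2 - 2.0, 1.6410373 * s2 - 1.2264489) + FEASIBILITY_MARGIN


def project_to_feasible(skewness: float, kurtosis: float) -> tuple[float, float]:
    """Euclidean projection of a (skewness, kurtosis) pair onto the
    feasible region {k >= min_feasible_kurtosis(s)}."""
    if kurtosis >= min_feasible_kurtosis(skewness):
        return skewness, kurtosis

    def dist2(s):
        g = min_feasible_kurtosis(s)
        return (s - skewness) ** 2 + (g - kurtosis) ** 2

    span = 2.0 + abs(skewness)
    res = optimize.minimize_scalar(
        dist2, bounds=(skewness - span, skewness + span), method="bounded",
        options={"xatol": 1e-10},
    )
    s = float(res.x)
    return s, min_feasible_kurtosis(s)


# --------------------------------------------------------------------------
# Target sampling


def _mvn_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray,
              n: int) -> np.ndarray:
    """PSD-tolerant multivariate normal draws (eigenvalue clipping)."""
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-9 * max(1.0, vals.max()):
        raise ValueError("covariance is not PSD within tolerance")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, len(mean)))
    return mean + z @ root.T


def sample_feature_targets(
    config: SyntheticCohortConfig, rng: np.random.Generator | None = None
) -> list[PatientTargets]:
    """Draw per-patient moment targets for the whole cohort.

    Per group, each targeted feature's sample has expectation equal to
    the configured group mean and dispersion equal to the configured
    group SD; infeasible (skewness, kurtosis) combinations are
    projected to the nearest feasible point.  Deterministic given the
    config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    corr = config.correlation_matrix()
    out: list[PatientTargets] = []
    counts = {"nonresponse": config.n_nonresponse, "response": config.n_response}
    idx = 0
    for group in GROUPS:
        stats_ = config.feature_targets[group]
        means = np.array([stats_[f][0] for f in TARGETED_FEATURES])
        sds = np.array([stats_[f][1] for f in TARGETED_FEATURES])
        cov = corr * np.outer(sds, sds)
        draws = _mvn_draw(rng, means, cov, counts[group])
        for row in draws:
            v = dict(zip(TARGETED_FEATURES, row))
            pre_sd = max(v["pre_SD"], SD_TARGET_FLOOR)
            post_sd = max(v["pre_SD"] + v["SD_change"], SD_TARGET_FLOOR)
            def shape(s, k):
                s = float(np.clip(s, -SKEWNESS_CAP, SKEWNESS_CAP))
                k = float(min(k, KURTOSIS_CAP))
                return project_to_feasible(s, k)

            pre_s, pre_k = shape(v["pre_skewness"], v["pre_kurtosis"])
            post_s, post_k = shape(
                v["pre_skewness"] + v["skewness_change"],
                v["pre_kurtosis"] + v["kurtosis_change"])
            idx += 1
            out.append(PatientTargets(
                patient_id=f"P{idx:04d}",
                group=group,
                pre=TimepointTargets(v["pre_mean"], pre_sd, pre_s, pre_k),
                post=TimepointTargets(
                    v["pre_mean"] + v["mean_change"], post_sd, post_s, post_k),
                pre_adc=v["pre_ADC"],
                post_adc=v["pre_ADC"] + v["ADC_change"],
            ))
    return out


# --------------------------------------------------------------------------
# Cubic power-method moment matching


def _poly_moments(b: float, c: float, d: float) -> tuple[float, float, float]:
    """Population variance, skewness and excess kurtosis of
    a + bZ + cZ^2 + dZ^3 with a = -c and Z standard normal."""
    var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
    skew = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
    kurt = 24 * (b * d + c * c * (1 + b * b + 28 * b * d)
                 + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d))
    if var > 0:
        skew /= var ** 1.5
        kurt /= var * var
    return var, skew, kurt


@lru_cache(maxsize=100_000)
def fleishman_coefficients(skewness: float, kurtosis: float) -> tuple[float, float, float]:
    """Cubic-transform coefficients (b, c, d) whose population moments
    are (0, 1, skewness, kurtosis); a = -c."""

    def residual(p):
        var, skew, kurt = _poly_moments(*p)
        return [var - 1.0, skew - skewness, kurt - kurtosis]

    starts = [(1.0, 0.05 * np.sign(skewness) or 0.0, 0.01),
              (0.9, 0.15 * np.sign(skewness) or 0.1, 0.05),
              (0.7, 0.2, 0.1), (1.0, 0.0, 0.0)]
    for x0 in starts:
        sol = optimize.least_squares(residual, x0, xtol=1e-14, ftol=1e-14)
        if np.max(np.abs(sol.fun)) < 1e-9:
            return tuple(float(x) for x in sol.x)
    raise MomentSolverError(
        f"no cubic transform for skewness={skewness:.4f}, "
        f"kurtosis={kurtosis:.4f}"
    )


def _sample_shape_moments(y: np.ndarray) -> tuple[float, float, float]:
    m = y.mean()
    ycent = y - m
    m2 = np.mean(ycent ** 2)
    m3 = np.mean(ycent ** 3)
    m4 = np.mean(ycent ** 4)
    return m2, m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0


def _match_empirical(z: np.ndarray, skewness: float, kurtosis: float):
    """Solve (b, c, d) so the realized sample of the cubic transform has
    exactly the target sample skewness and kurtosis (mean and SD are
    fixed afterwards by an affine map)."""
    z2, z3 = z * z, z ** 3

    def residual(p):
        b, c, d = p
        y = b * z + c * (z2 - 1.0) + d * z3
        m2, skew, kurt = _sample_shape_moments(y)
        return [m2 - 1.0, skew - skewness, kurt - kurtosis]

    x0 = fleishman_coefficients(round(skewness, 9), round(kurtosis, 9))
    for start in (x0, (1.0, 0.0, 0.0), (0.8, 0.1 * np.sign(skewness), 0.05)):
        sol = optimize.least_squares(residual, start, xtol=1e-14, ftol=1e-14)
        if np.max(np.abs(sol.fun[1:])) < 1e-6:
            b, c, d = sol.x
            return b * z + c * (z2 - 1.0) + d * z3
    raise MomentSolverError("empirical moment matching did not converge")


# --------------------------------------------------------------------------
# ROI geometry


def _roi_geometry(rng: np.random.Generator, shape: tuple[int, int]):
    """Random ellipse (center, semi-axes, angle) filling a good part of
    the field of view."""
    h, w = shape
    scale = min(h, w)
    center = (h / 2 + rng.uniform(-0.03, 0.03) * h,
              w / 2 + rng.uniform(-0.03, 0.03) * w)
    axes = (rng.uniform(0.30, 0.42) * scale / 1.0,
            rng.uniform(0.22, 0.34) * scale / 1.0)
    angle = rng.uniform(0, np.pi)
    return center, axes, angle


def _normalized_radius(shape, center, axes, angle):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dy + sa * dx) / axes[0]
    v = (-sa * dy + ca * dx) / axes[1]
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    return rho, theta


def ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rho, _ = _normalized_radius(shape, center, axes, angle)
    return rho <= 1.0


def jittered_mask(
    shape, center, axes, angle, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Ellipse mask with a smooth random radial boundary perturbation of
    fractional amplitude ``jitter`` (a low-order Fourier series in the
    boundary angle).  With jitter > 0 the result is guaranteed to
    differ from the unperturbed mask in at least one pixel."""
    base = ellipse_mask(shape, center, axes, angle)
    if jitter <= 0:
        return base.copy()
    rho, theta = _normalized_radius(shape, center, axes, angle)
    amps = rng.standard_normal(3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    s = sum(a * np.cos((m + 1) * theta + ph)
            for m, (a, ph) in enumerate(zip(amps, phases)))
    peak = np.abs(s).max()
    if peak > 0:
        s = s / peak
    mask = rho <= 1.0 + jitter * s
    if np.array_equal(mask, base):
        # force a minimal difference: toggle the first boundary pixel
        boundary = np.argwhere(base & (rho > 1.0 - 2.0 / min(axes)))
        if len(boundary) == 0:
            boundary = np.argwhere(base)
        i, j = boundary[0]
        mask = mask.copy()
        mask[i, j] = ~mask[i, j]
    return mask


# --------------------------------------------------------------------------
# Pixel synthesis


def synthesize_roi_image(
    targets: PatientTargets,
    timepoint: str,
    roi_shape: tuple[int, int] = (64, 64),
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
    max_retries: int = 8,
) -> tuple[ADCMap, ROIMask, dict]:
    """Realize one ROI's moment targets as pixel data.

    Masked pixels are a cubic polynomial transform of standard normal
    noise, moment-matched so the empirical mean and SD agree with the
    targets to 1e-2 relative and skewness/kurtosis to 0.1 absolute
    (in practice to solver precision).  The background outside the ROI
    is a smooth positive field at ~60% of the ROI mean.  If the
    transform produces non-positive pixels the noise is redrawn; as a
    last resort an affine floor shift is applied and recorded in the
    returned metadata.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t: TimepointTargets = getattr(targets, timepoint)
    if mask is None:
        center, axes, angle = _roi_geometry(rng, roi_shape)
        mask = ellipse_mask(roi_shape, center, axes, angle)
    else:
        roi_shape = mask.shape
    n = int(mask.sum())
    sd_raw = t.sd / SD_UNIT_FACTOR

    floor_shift = 0.0
    if sd_raw <= 1e-12:
        inside = np.full(n, t.mean)
    else:
        if t.kurtosis < min_feasible_kurtosis(t.skewness) - FEASIBILITY_MARGIN:
            raise MomentSolverError(
                f"infeasible target moments (mean={t.mean:.4f}, SD={t.sd:.4f}, "
                f"skewness={t.skewness:.4f}, kurtosis={t.kurtosis:.4f})"
            )
        inside = None
        for _ in range(max_retries):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std()
            try:
                y = _match_empirical(z, t.skewness, t.kurtosis)
            except MomentSolverError:
                continue
            y = (y - y.mean()) / y.std()
            cand = t.mean + sd_raw * y
            if cand.min() > 0:
                inside = cand
                break
            if inside is None:
                inside = cand  # fallback, floor-shifted below
        if inside is None:
            raise MomentSolverError(
                f"moment solver failed for target quadruple (mean={t.mean:.4f}, "
                f"SD={t.sd:.4f}, skewness={t.skewness:.4f}, "
                f"kurtosis={t.kurtosis:.4f})"
            )
        if inside.min() <= 0:
            floor_shift = 1e-4 - inside.min()
            inside = inside + floor_shift

    background_level = max(0.6 * t.mean, 1e-4)
    pixels = np.full(roi_shape, background_level)
    pixels += 0.05 * background_level * np.abs(rng.standard_normal(roi_shape))
    pixels[mask] = inside
    adc_map = ADCMap(pixels=pixels, patient_id=targets.patient_id,
                     timepoint=timepoint)
    meta = {
        "floor_shift": floor_shift,
        "n_pixels": n,
        "targets": {"mean": t.mean, "sd": t.sd,
                    "skewness": t.skewness, "kurtosis": t.kurtosis},
    }
    return adc_map, ROIMask(mask=mask, reader_id="reader1"), meta


# --------------------------------------------------------------------------
# Subjective reader calls


def simulate_reader_calls(
    labels, sens: float, spec: float,
    seed: int | np.random.Generator = 0, exact: bool = False,
) -> np.ndarray:
    """Simulate one reader's binary nonresponse calls.

    Each true non-responder is called positive with probability
    ``sens`` and each responder with probability ``1 - spec``,
    independently.  With ``exact=True`` the number of true/false
    positives is fixed at the rounded expected counts (a seeded choice
    of which patients), realizing the operating point exactly.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sens and spec must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arr = np.asarray(labels)
    y = (arr == "nonresponse").astype(int) if arr.dtype.kind in "OUS" \
        else (arr != 0).astype(int)
    calls = np.zeros_like(y)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if exact:
        n_tp = int(round(sens * pos_idx.size))
        n_fp = int(round((1 - spec) * neg_idx.size))
        calls[rng.choice(pos_idx, n_tp, replace=False)] = 1
        calls[rng.choice(neg_idx, n_fp, replace=False)] = 1
    else:
        calls[pos_idx] = rng.random(pos_idx.size) < sens
        calls[neg_idx] = rng.random(neg_idx.size) < (1 - spec)
    return calls


# --------------------------------------------------------------------------
# Whole-cohort generation


@dataclass
class SyntheticPatient:
    patient_id: str
    group: str
    targets: PatientTargets
    pre_map: ADCMap
    post_map: ADCMap
    pre_mask: ROIMask
    pre_mask_reader2: ROIMask
    post_mask: ROIMask
    post_mask_reader2: ROIMask
    covariates: dict
    adc_readings: dict  # {"pre": (r1, r2), "post": (r1, r2)}
    metadata: dict


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    manifest: pd.DataFrame
    config: SyntheticCohortConfig

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["group"].to_numpy()


def _sample_covariates(rng: np.random.Generator, group: str) -> dict:
    dist = COVARIATE_DISTRIBUTIONS[group]
    age_mu, age_sd = dist["age"]
    ct_cats, ct_p = zip(*dist["cT"].items())
    cn_cats, cn_p = zip(*dist["cN"].items())
    return {
        "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 90)),
        "sex": "M" if rng.random() < dist["p_male"] else "F",
        "cT": rng.choice(ct_cats, p=np.array(ct_p) / sum(ct_p)),
        "cN": rng.choice(cn_cats, p=np.array(cn_p) / sum(cn_p)),
    }


def generate_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path | None = None,
    cohort_name: str = "primary",
    intensity_scale: float = 1.0,
    intensity_offset: float = 0.0,
) -> SyntheticCohort:
    """Generate a fully self-contained synthetic cohort.

    Per patient: pre/post ADC maps realizing the sampled moment
    targets, a first- and a jittered second-reader ROI per timepoint,
    dual-reader manual ADC measurements, simulated subjective reader
    calls, clinical covariates and the binary ground-truth label.  With
    ``out_dir`` the images, masks and a manifest CSV are written to
    disk (partial outputs are removed on failure).  ``intensity_scale``
    and ``intensity_offset`` apply a global affine perturbation to the
    pixel data, emulating a different scanner for an external cohort.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    ss_targets, ss_images, ss_cov, ss_readers = root_ss.spawn(4)
    targets = sample_feature_targets(
        config, np.random.default_rng(ss_targets))

    img_rngs = [np.random.default_rng(s)
                for s in ss_images.spawn(len(targets))]
    cov_rng = np.random.default_rng(ss_cov)
    reader_rng = np.random.default_rng(ss_readers)

    patients: list[SyntheticPatient] = []
    for t, rng in zip(targets, img_rngs):
        per_tp = {}
        meta = {}
        for tp in ("pre", "post"):
            center, axes, angle = _roi_geometry(rng, config.roi_shape)
            mask1 = ellipse_mask(config.roi_shape, center, axes, angle)
            mask2 = jittered_mask(config.roi_shape, center, axes, angle,
                                  config.reader2_mask_jitter, rng)
            adc_map, roi, m = synthesize_roi_image(
                t, tp, config.roi_shape, seed=rng, mask=mask1)
            if intensity_scale != 1.0 or intensity_offset != 0.0:
                adc_map.pixels = np.clip(
                    adc_map.pixels * intensity_scale + intensity_offset,
                    0.0, None)
            per_tp[tp] = (adc_map, roi,
                          ROIMask(mask=mask2, reader_id="reader2"))
            meta[tp] = m
        noise = config.reader_adc_noise
        adc_readings = {
            "pre": (t.pre_adc + noise * rng.standard_normal(),
                    t.pre_adc + noise * rng.standard_normal()),
            "post": (t.post_adc + noise * rng.standard_normal(),
                     t.post_adc + noise * rng.standard_normal()),
        }
        patients.append(SyntheticPatient(
            patient_id=t.patient_id,
            group=t.group,
            targets=t,
            pre_map=per_tp["pre"][0], post_map=per_tp["post"][0],
            pre_mask=per_tp["pre"][1], pre_mask_reader2=per_tp["pre"][2],
            post_mask=per_tp["post"][1], post_mask_reader2=per_tp["post"][2],
            covariates=_sample_covariates(cov_rng, t.group),
            adc_readings=adc_readings,
            metadata=meta,
        ))

    labels = np.array([p.group for p in patients])
    reader_calls = {}
    for reader, (sens, spec) in config.reader_operating_points.items():
        reader_calls[reader] = simulate_reader_calls(
            labels, sens, spec, seed=reader_rng)

    rows = []
    for i, p in enumerate(patients):
        row = {
            "patient_id": p.patient_id,
            "cohort": cohort_name,
            "group": p.group,
            "pre_image": "", "pre_mask": "", "pre_mask_reader2": "",
            "post_image": "", "post_mask": "", "post_mask_reader2": "",
            "age": round(p.covariates["age"], 1),
            "sex": p.covariates["sex"],
            "cT": p.covariates["cT"],
            "cN": p.covariates["cN"],
            "pre_adc_reader1": p.adc_readings["pre"][0],
            "pre_adc_reader2": p.adc_readings["pre"][1],
            "post_adc_reader1": p.adc_readings["post"][0],
            "post_adc_reader2": p.adc_readings["post"][1],
        }
        for reader in config.reader_operating_points:
            row[f"mrtrg_{reader}"] = int(reader_calls[reader][i])
        rows.append(row)
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        _write_cohort(Path(out_dir), patients, manifest, config)
    return SyntheticCohort(patients=patients, manifest=manifest, config=config)


def _write_cohort(out_dir: Path, patients, manifest: pd.DataFrame,
                  config: SyntheticCohortConfig) -> None:
    from . import imgio

    ext = ".png" if config.image_format == "png" else ".nii"
    created = not out_dir.exists()
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(patients):
            paths = {}
            for tp, amap, m1, m2 in (
                ("pre", p.pre_map, p.pre_mask, p.pre_mask_reader2),
                ("post", p.post_map, p.post_mask, p.post_mask_reader2),
            ):
                img = out_dir / "images" / f"{p.patient_id}_{tp}{ext}"
                msk1 = out_dir / "masks" / f"{p.patient_id}_{tp}_r1{ext}"
                msk2 = out_dir / "masks" / f"{p.patient_id}_{tp}_r2{ext}"
                imgio.write_adc_map(img, amap.pixels)
                imgio.write_mask(msk1, m1.mask)
                imgio.write_mask(msk2, m2.mask)
                paths[f"{tp}_image"] = str(img.relative_to(out_dir))
                paths[f"{tp}_mask"] = str(msk1.relative_to(out_dir))
                paths[f"{tp}_mask_reader2"] = str(msk2.relative_to(out_dir))
            for k, v in paths.items():
                manifest.loc[i, k] = v
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            warnings.warn(f"partial outputs left under {out_dir}",
                          RuntimeWarning)
        raise
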