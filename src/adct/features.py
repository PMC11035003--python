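"""First-order texture features and manual ADC values on masked ADC maps.

An ADC (apparent diffusion coefficient) map is a quantitative
diffusion-MRI image; here a single 2D slice in units of 10^-3 mm^2/s
with a binary tumor ROI mask.  The texture features are pure histogram
statistics of the masked pixel values — mean, SD, variance, skewness,
excess kurtosis and entropy — computed at the pre- and post-treatment
timepoints plus their post-minus-pre changes.

Reporting conventions (fixed throughout the package):

* mean in 10^-3 mm^2/s; SD reported in 10^-5 mm^2/s (raw SD x 100);
  variance is the square of the reported SD.
* skewness = m3 / m2^1.5 and excess kurtosis = m4 / m2^2 - 3 with
  population (biased) moments; sample-size corrections are negligible
  at ROI sizes of ~10^3 pixels.
* entropy = sum_i p_i * log2 p_i over a 256-bin histogram of the ROI
  values min-max scaled to [0, 255] (so entropy is <= 0; empty bins
  contribute 0).  The signed convention keeps entropy on the same scale
  as the reference cohort reports.
* a constant ROI yields SD = variance = 0 and skewness/kurtosis/entropy
  reported as 0 with a degeneracy flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import FEATURE_NAMES

#: raw (10^-3 mm^2/s) -> reported SD units (10^-5 mm^2/s)
SD_UNIT_FACTOR = 100.0

#: gray levels of the ROI histogram used for entropy
N_GRAY_LEVELS = 256

#: minimum number of foreground pixels for a usable ROI
DEFAULT_PIXEL_FLOOR = 16


class MaskError(ValueError):
    """Raised for unusable ROI masks (wrong shape or below pixel floor)."""


@dataclass
class ADCMap:
    """A single-timepoint 2D ADC map in physical units of 10^-3 mm^2/s."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    patient_id: str = ""
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ADC map must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ADC map contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("ADC values must be non-negative")


@dataclass
class ROIMask:
    """Binary tumor region-of-interest mask for one ADC map."""

    mask: np.ndarray
    reader_id: str = "reader1"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be a 2D array")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FirstOrderStats:
    """The six histogram statistics of one masked ROI."""

    mean: float
    sd: float          # 10^-5 mm^2/s
    variance: float    # (10^-5 mm^2/s)^2
    skewness: float
    kurtosis: float    # excess
    entropy: float     # sum(p log2 p), <= 0
    degenerate: bool = False


@dataclass
class FeatureVector:
    """All 21 per-patient quantities: 18 texture features + 3 manual ADC values."""

    values: dict[str, float] = field(default_factory=dict)
    label: str | None = None
    patient_id: str = ""
    degenerate: bool = False

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict[str, float]:
        row = dict(self.values)
        if self.label is not None:
            row["label"] = self.label
        return row


def masked_pixels(
    adc_map: ADCMap, mask: ROIMask, pixel_floor: int = DEFAULT_PIXEL_FLOOR
) -> np.ndarray:
    """Extract the ADC values at mask-foreground positions, row-major order.

    Raises
    ------
    MaskError
        If the mask shape differs from the map or the foreground has
        fewer than ``pixel_floor`` pixels.
    """
    if adc_map.pixels.shape != mask.mask.shape:
        raise MaskError(
            f"mask shape {mask.mask.shape} does not match map shape "
            f"{adc_map.pixels.shape}"
        )
    if mask.n_pixels < pixel_floor:
        raise MaskError(
            f"mask below pixel floor: {mask.n_pixels} < {pixel_floor}"
        )
    return adc_map.pixels[mask.mask]


def histogram_entropy(values: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> float:
    """Signed entropy sum(p log2 p) of the min-max discretized ROI histogram.

    Values are scaled to ``[0, n_levels - 1]`` by the per-ROI min-max
    range; a zero-width range puts all mass in one bin (entropy 0).
    Because binning is per-ROI min-max, entropy is invariant to affine
    rescaling of the pixel values.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return 0.0
    levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(int)
    levels[levels == n_levels] = n_levels - 1
    counts = np.bincount(levels, minlength=n_levels)
    p = counts[counts > 0] / values.size
    return float(np.sum(p * np.log2(p)))


def first_order_stats(values: np.ndarray) -> FirstOrderStats:
    """Compute mean, SD, variance, skewness, excess kurtosis and entropy.

    ``values`` are ROI pixel values in 10^-3 mm^2/s; at least two values
    are required.  A zero-variance ROI is flagged degenerate and the
    shape statistics are returned as 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for first-order statistics")
    mean = float(values.mean())
    m2 = float(np.mean((values - mean) ** 2))
    if m2 <= 0.0:
        return FirstOrderStats(mean, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    sd = float(np.sqrt(m2)) * SD_UNIT_FACTOR
    m3 = float(np.mean((values - mean) ** 3))
    m4 = float(np.mean((values - mean) ** 4))
    skew = m3 / m2 ** 1.5
    kurt = m4 / m2 ** 2 - 3.0
    return FirstOrderStats(
        mean=mean,
        sd=sd,
        variance=sd * sd,
        skewness=skew,
        kurtosis=kurt,
        entropy=histogram_entropy(values),
    )


def _stats_as_dict(prefix: str, s: FirstOrderStats) -> dict[str, float]:
    return {
        f"{prefix}_mean": s.mean,
        f"{prefix}_SD": s.sd,
        f"{prefix}_variance": s.variance,
        f"{prefix}_skewness": s.skewness,
        f"{prefix}_kurtosis": s.kurtosis,
        f"{prefix}_entropy": s.entropy,
    }


def compute_feature_vector(
    pre_map: ADCMap,
    pre_mask: ROIMask,
    post_map: ADCMap,
    post_mask: ROIMask,
    pixel_floor: int = DEFAULT_PIXEL_FLOOR,
) -> FeatureVector:
    """Texture part of the feature vector: six statistics at both
    timepoints plus their post-minus-pre changes."""
    pre = first_order_stats(masked_pixels(pre_map, pre_mask, pixel_floor))
    post = first_order_stats(masked_pixels(post_map, post_mask, pixel_floor))
    values = {**_stats_as_dict("pre", pre), **_stats_as_dict("post", post)}
    for stat in ("mean", "SD", "variance", "skewness", "kurtosis", "entropy"):
        values[f"{stat}_change"] = values[f"post_{stat}"] - values[f"pre_{stat}"]
    return FeatureVector(
        values=values,
        patient_id=pre_map.patient_id,
        degenerate=pre.degenerate or post.degenerate,
    )


def mean_adc(
    adc_map: ADCMap, mask: ROIMask, pixel_floor: int = DEFAULT_PIXEL_FLOOR
) -> float:
    """Arithmetic mean ADC of the masked region (10^-3 mm^2/s)."""
    return float(masked_pixels(adc_map, mask, pixel_floor).mean())


def average_reader_adc(adc_reader1: float | None, adc_reader2: float | None) -> float:
    """Average the two readers' manual ADC measurements.

    Both readers must be present: there is no silent single-reader
    fallback, mirroring the dual-reader measurement protocol.
    """
    if adc_reader1 is None or adc_reader2 is None:
        raise ValueError("both readers' ADC values are required")
    return 0.5 * (float(adc_reader1) + float(adc_reader2))


def adc_change(pre_adc: float, post_adc: float) -> float:
    """ADC_change = post_ADC - pre_ADC."""
    return float(post_adc) - float(pre_adc)


def feature_table_columns() -> list[str]:
    """Canonical column order of the per-patient feature CSV."""
    return list(FEATURE_NAMES)
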