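"""First-order tumor imaging features.

Ten features per delineated tumor: six conventional — maximum SUV, mean
SUV, median SUV, metabolic tumor volume (MTV, cm³), total lesion glycolysis
(TLG = MTV × mean SUV, grams under the unit-density convention), and
coefficient of variation of SUV (CoV, population SD / mean) — and four from
the SUV intensity histogram: kurtosis, skewness, entropy (bits) and
uniformity.

The histogram uses a fixed number of equal-width bins (default 64) over the
VOI's [min, max]; skewness/kurtosis are moments of the discretized
distribution on bin centers, kurtosis reported as excess (normal = 0).  CoV
is computed on the raw voxel values, not the histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .volume import SUVVolume, VOIMask

__all__ = [
    "HistogramConfig",
    "TumorFeatureSet",
    "conventional_features",
    "intensity_histogram",
    "histogram_features",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "max_suv",
    "mean_suv",
    "median_suv",
    "mtv_cm3",
    "tlg_g",
    "cov_suv",
    "kurtosis",
    "skewness",
    "entropy_bits",
    "uniformity",
)


@dataclass
class HistogramConfig:
    """Discretization of the SUV intensity histogram."""

    n_bins: int = 64
    bin_mode: str = "fixed_bin_number"
    log_base: float = 2.0
    excess_kurtosis: bool = True
    ddof: int = 0  # population SD for CoV; set 1 for sample SD

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.bin_mode != "fixed_bin_number":
            raise ValueError(f"unsupported bin_mode {self.bin_mode!r}")


@dataclass
class TumorFeatureSet:
    max_suv: float
    mean_suv: float
    median_suv: float
    mtv_cm3: float
    tlg_g: float
    cov_suv: float
    kurtosis: float
    skewness: float
    entropy_bits: float
    uniformity: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _masked_values(volume: SUVVolume, mask: VOIMask) -> np.ndarray:
    mask.check_aligned(volume)
    vals = volume.values[mask.values]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return vals


def conventional_features(volume: SUVVolume, mask: VOIMask, ddof: int = 0):
    """Max/mean/median SUV, MTV (cm³), TLG (g), CoV of the masked voxels."""
    vals = _masked_values(volume, mask)
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("mean SUV is zero; CoV undefined")
    mtv = vals.size * volume.voxel_volume_mm3 / 1000.0
    return (
        float(vals.max()),
        mean,
        float(np.median(vals)),
        float(mtv),
        float(mtv * mean),
        float(vals.std(ddof=ddof) / mean),
    )


def intensity_histogram(
    volume: SUVVolume, mask: VOIMask, config: HistogramConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Probability vector over equal-width bins of the masked SUVs.

    Bins partition ``[min, max]`` into ``n_bins`` half-open intervals, the
    last interval closed.  Returns ``(p, bin_centers)``.  If all values are
    equal the whole mass sits in the first bin.
    """
    config = config or HistogramConfig()
    vals = _masked_values(volume, mask)
    n = config.n_bins
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        p = np.zeros(n)
        p[0] = 1.0
        centers = np.full(n, lo)
        return p, centers
    width = (hi - lo) / n
    idx = np.minimum((np.floor((vals - lo) / width)).astype(int), n - 1)
    p = np.bincount(idx, minlength=n).astype(float) / vals.size
    centers = lo + (np.arange(n) + 0.5) * width
    return p, centers


def histogram_features(
    p: np.ndarray, bin_values: np.ndarray, config: HistogramConfig | None = None
):
    """(kurtosis, skewness, entropy_bits, uniformity) of a discretized distribution.

    Entropy is ``−Σ p log2 p`` over occupied bins; uniformity is ``Σ p²``.
    Skewness/kurtosis are standardized central moments on ``bin_values``
    weighted by ``p``; a degenerate distribution (zero variance) returns 0
    for both with a warning.
    """
    config = config or HistogramConfig()
    p = np.asarray(p, dtype=float)
    if p.sum() == 0:
        raise ValueError("probability vector is all zero")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("probability vector must be normalized")
    pos = p[p > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    if config.log_base != 2.0:
        entropy *= np.log(2.0) / np.log(config.log_base)
    uniformity = float((p**2).sum())

    x = np.asarray(bin_values, dtype=float)
    mu = float((p * x).sum())
    m2 = float((p * (x - mu) ** 2).sum())
    if m2 == 0:
        warnings.warn("degenerate histogram: skewness/kurtosis set to 0", RuntimeWarning)
        return 0.0, 0.0, entropy, uniformity
    m3 = float((p * (x - mu) ** 3).sum())
    m4 = float((p * (x - mu) ** 4).sum())
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - (3.0 if config.excess_kurtosis else 0.0)
    return kurt, skew, entropy, uniformity


def extract_features(
    volume: SUVVolume, mask: VOIMask, config: HistogramConfig | None = None
) -> TumorFeatureSet:
    """All 10 first-order features of one delineated tumor."""
    config = config or HistogramConfig()
    mx, mean, med, mtv, tlg, cov = conventional_features(volume, mask, ddof=config.ddof)
    p, centers = intensity_histogram(volume, mask, config)
    kurt, skew, entropy, uniformity = histogram_features(p, centers, config)
    return TumorFeatureSet(
        max_suv=mx,
        mean_suv=mean,
        median_suv=med,
        mtv_cm3=mtv,
        tlg_g=tlg,
        cov_suv=cov,
        kurtosis=kurt,
        skewness=skew,
        entropy_bits=entropy,
        uniformity=uniformity,
    )
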