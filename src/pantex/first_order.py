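"""First-order (histogram) features of a segmented region.

These statistics describe the marginal distribution of HU values inside the
ROI, ignoring spatial arrangement: mean attenuation, standard deviation,
variance, skewness, kurtosis, histogram entropy and histogram uniformity
("homogeneity").

Conventions
-----------
* SD and variance use the n−1 (sample) denominator.
* Skewness is the adjusted Fisher–Pearson coefficient (the SPSS/Excel
  convention, bias-corrected G1); kurtosis defaults to the Pearson
  non-excess moment ratio m4/m2² (a normal distribution gives ≈ 3).
  Both conventions are selectable.
* Entropy and homogeneity are computed on a fixed-width histogram
  (default 1 HU bins, left-closed right-open, edges anchored at integer
  multiples of the width).  Entropy defaults to nats; for a Gaussian HU
  field of SD σ with 1-HU bins it approaches the differential entropy
  ½·ln(2πeσ²).  Homogeneity is the histogram uniformity Σ p_b² (1 for a
  constant region, 1/k for k uniformly occupied bins).

Statistics whose sample-size preconditions are not met (SD with n < 2,
skewness with n < 3, kurtosis with n < 4, and skewness/kurtosis of a
zero-variance sample) are returned as NaN, the pipeline's undefined marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volumes import SegmentedRegion

__all__ = ["Histogram", "FirstOrderFeatures", "build_histogram", "first_order"]

_LOG = {"ln": np.log, "log2": np.log2, "log10": np.log10}


@dataclass(frozen=True)
class Histogram:
    """Fixed-width HU histogram of a region.

    ``bin_edges`` has ``len(counts) + 1`` entries, each an integer multiple
    of the bin width, covering every observed value with left-closed
    right-open bins.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class FirstOrderFeatures:
    mean_attenuation: float  # HU
    sd: float                # HU
    variance: float          # HU^2
    skewness: float
    kurtosis: float
    entropy: float           # nats by default
    homogeneity: float       # histogram uniformity, (0, 1]

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_attenuation": self.mean_attenuation,
            "sd": self.sd,
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "entropy": self.entropy,
            "homogeneity": self.homogeneity,
        }


def build_histogram(region: SegmentedRegion, bin_width: float = 1.0) -> Histogram:
    """Histogram of ROI voxel values with deterministic edge placement.

    Edges sit at integer multiples of ``bin_width``; a value x falls in bin
    ``floor(x / bin_width)``, so binning is left-closed right-open and
    independent of the sample (no data-driven edge jitter between runs).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    values = np.asarray(region.voxel_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty region: no voxels to histogram")
    lo = math.floor(values.min() / bin_width)
    hi = math.floor(values.max() / bin_width)
    n_bins = hi - lo + 1
    idx = np.floor(values / bin_width).astype(np.int64) - lo
    counts = np.bincount(idx, minlength=n_bins)
    edges = (np.arange(lo, hi + 2, dtype=float)) * bin_width
    return Histogram(bin_edges=edges, counts=counts, bin_width=float(bin_width))


def _skewness(values: np.ndarray, convention: str) -> float:
    n = values.size
    if n < 3 or np.var(values) == 0:
        return float("nan")
    if convention == "adjusted":  # bias-corrected Fisher–Pearson (SPSS G1)
        return float(sps.skew(values, bias=False))
    if convention == "moment":  # plain g1 = m3 / m2^(3/2)
        return float(sps.skew(values, bias=True))
    raise ValueError(f"unknown skewness convention: {convention!r}")


def _kurtosis(values: np.ndarray, convention: str) -> float:
    n = values.size
    if n < 4 or np.var(values) == 0:
        return float("nan")
    if convention == "pearson":  # non-excess m4/m2^2, normal -> 3
        return float(sps.kurtosis(values, fisher=False, bias=True))
    if convention == "excess":  # Fisher, normal -> 0
        return float(sps.kurtosis(values, fisher=True, bias=True))
    raise ValueError(f"unknown kurtosis convention: {convention!r}")


def first_order(
    region: SegmentedRegion,
    bin_width: float = 1.0,
    log_base: str = "ln",
    skewness_convention: str = "adjusted",
    kurtosis_convention: str = "pearson",
) -> FirstOrderFeatures:
    """Compute the seven first-order features of a segmented region.

    Parameters
    ----------
    region : SegmentedRegion
    bin_width : float
        Histogram bin width in HU for entropy/homogeneity (default 1 HU).
    log_base : {"ln", "log2", "log10"}
        Logarithm used for entropy (default natural log, i.e. nats).
    skewness_convention : {"adjusted", "moment"}
    kurtosis_convention : {"pearson", "excess"}
    """
    values = np.asarray(region.voxel_values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("empty region")
    log = _LOG[log_base]

    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n >= 2 else float("nan")
    variance = sd * sd if n >= 2 else float("nan")

    hist = build_histogram(region, bin_width=bin_width)
    p = hist.probabilities
    p = p[p > 0]
    entropy = float(-np.sum(p * log(p))) if p.size > 1 else 0.0
    homogeneity = float(np.sum(p * p))

    return FirstOrderFeatures(
        mean_attenuation=mean,
        sd=sd,
        variance=variance,
        skewness=_skewness(values, skewness_convention),
        kurtosis=_kurtosis(values, kurtosis_convention),
        entropy=entropy,
        homogeneity=homogeneity,
    )
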