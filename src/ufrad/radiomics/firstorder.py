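"""First-order intensity statistics (17 descriptors).

Histogram-based descriptors (entropy, uniformity) use the same
fixed-bin-count discretization as the texture features.
"""

from __future__ import annotations

import numpy as np

from ufrad.radiomics.preprocess import discretize

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "energy",
    "total_energy",
    "entropy",
    "uniformity",
    "mad",
    "rms",
    "p10",
    "p90",
)


def extract_first_order(
    vol: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
) -> dict[str, float]:
    """17 first-order statistics of the in-mask intensities.

    Variance/SD use the population convention; skewness and kurtosis
    (Fisher, i.e. normal = 0) are defined as 0 for constant regions.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(vol, dtype=float)[mask]
    if x.size < 2:
        raise ValueError("need at least 2 voxels for first-order statistics")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    centered = x - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4 - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    levels = discretize(vol, mask, n_bins)[mask]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))
    voxel_volume = float(np.prod(spacing_mm))
    energy = float(np.sum(x**2))
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "std": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "total_energy": energy * voxel_volume,
        "entropy": entropy,
        "uniformity": uniformity,
        "mad": float(np.mean(np.abs(centered))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }
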