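"""First-order intensity statistics (18 features) on raw in-mask HU values.

Entropy and Uniformity are computed on the fixed-bin-width histogram; all
other features use the raw values.  Moments are population moments;
skewness/kurtosis of a constant ROI are defined as 0 (degenerate case,
logged).  Kurtosis is not excess-corrected (the normal distribution scores 3).
"""

from __future__ import annotations

import logging

import numpy as np

from .discretization import DiscretizationSpec, discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

logger = logging.getLogger(__name__)

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float = 1.0,
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """The 18 first-order features of the in-mask voxel values."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(values, dtype=float)[mask]
    n = x.size

    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    if m2 > 0:
        skewness = float(np.mean((x - mean) ** 3)) / m2**1.5
        kurtosis = float(np.mean((x - mean) ** 4)) / m2**2
    else:
        logger.debug("constant ROI: skewness/kurtosis set to 0")
        skewness = 0.0
        kurtosis = 0.0

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    levels, _ = discretize(values, mask, disc)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Variance": m2,
        "Uniformity": uniformity,
    }
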