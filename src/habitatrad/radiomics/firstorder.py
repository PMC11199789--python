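"""The 18 first-order intensity statistics.

Entropy and uniformity are computed on the same fixed-bin-width histogram
used for the texture matrices.  Moments are population moments (divisor N).
Zero-variance regions return skewness = kurtosis = 0 by convention so no
NaN ever enters a feature table.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["first_order_features", "FIRST_ORDER_NAMES"]

FIRST_ORDER_NAMES: tuple[str, ...] = (
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
    arr: np.ndarray,
    mask: np.ndarray,
    bin_width: float,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(arr, dtype=np.float64)[mask]
    if x.size == 0:
        raise ValueError("mask is empty")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = np.sqrt(var)

    disc = discretize(arr, mask, bin_width)
    p = np.bincount(disc.inmask_levels())[1:] / n
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p * p).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / sd**4)
    else:
        skew = 0.0
        kurt = 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
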