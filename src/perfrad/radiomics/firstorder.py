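"""First-order (intensity histogram) features.

Moments and order statistics are computed on the raw in-mask intensities;
entropy and uniformity use the discretized histogram (log base 2).
Degenerate fallbacks: a constant (or single-voxel) region has variance 0,
skewness 0, kurtosis 0, entropy 0, uniformity 1.
"""

from __future__ import annotations

import numpy as np

from perfrad.radiomics.discretize import DiscretizedImage

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
    "Skewness", "Kurtosis", "Energy", "TotalEnergy", "Entropy",
    "Uniformity", "RootMeanSquared", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "Percentile10", "Percentile90",
    "InterquartileRange",
)


def first_order_features(
    image: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizedImage,
    voxel_volume: float = 1.0,
) -> dict:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(image, dtype=float)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    centred = x - mean
    if sd > 0:
        skew = float((centred ** 3).mean() / sd ** 3)
        kurt = float((centred ** 4).mean() / sd ** 4)
    else:
        skew, kurt = 0.0, 0.0

    counts = np.bincount(disc.in_mask(), minlength=disc.n_levels + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (x ** 2).sum()),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(centred).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
    }
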