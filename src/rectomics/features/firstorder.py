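"""First-order intensity statistics (18 descriptors).

All moments are population moments over the in-mask voxels of the
(possibly filtered) image.  Entropy and uniformity are computed on the
fixed-bin-width histogram, everything else on the raw intensities.
Kurtosis is the raw fourth standardized moment (3 for a Gaussian), not
excess kurtosis.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize


def firstorder_features(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 10.0,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(values, dtype=np.float64)[mask]
    n = x.size
    mean = x.mean()
    var = x.var()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    labels = discretize(values, mask, bin_width, warn_bin_count=False)[mask]
    p = np.bincount(labels)[1:].astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        z = x - mean
        skew = float((z**3).mean() / var**1.5)
        kurt = float((z**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": uniformity,
    }
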