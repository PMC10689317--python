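"""First-order (intensity histogram) statistics on the in-ROI voxel values.

Conventions follow the common radiomics-platform definitions: population
variance (divide by N), non-excess kurtosis, robust MAD computed on the
values between the 10th and 90th percentile inclusive, and entropy /
uniformity computed on a fixed-bin-width histogram.
"""

from __future__ import annotations

import numpy as np


def first_order(values, bin_width: float = 5.0) -> dict[str, float]:
    """Compute the standard first-order feature set on a 1-D value array.

    Parameters
    ----------
    values
        In-ROI intensities (at least one voxel).
    bin_width
        Histogram bin width used for Entropy and Uniformity only.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first_order requires at least one voxel")
    n = x.size
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    sd = float(np.sqrt(var))
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0

    # histogram probabilities with the same fixed bin width as texture discretization
    nbins = int(np.floor((x.max() - x.min()) / bin_width)) + 1
    counts = np.bincount(np.floor((x - x.min()) / bin_width).astype(int), minlength=nbins)
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Variance": var,
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(x**2)),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RMAD": rmad,
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Entropy": entropy,
        "Uniformity": uniformity,
    }
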