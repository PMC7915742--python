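"""First-order (intensity histogram) features, 18 in total.

Formulas follow the standard image-biomarker definitions.  Entropy and
Uniformity operate on the fixed-bin-width histogram; moments are population
(not sample) moments.  Features whose formula degenerates on a constant VOI
(Skewness, Kurtosis) return NaN, the flagged-undefined sentinel that
downstream repeatability scoring excludes pairwise.
"""

from __future__ import annotations

import numpy as np

from .discretize import DEFAULT_BIN_WIDTH, discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

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
    voxel_volume_mm3: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, float]:
    """The 18 first-order features of a 1D vector of in-VOI intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty VOI")
    n = x.size

    mean = x.mean()
    var = x.var()  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # histogram probabilities on the fixed-bin-width grid
    disc = discretize(x.reshape(1, 1, -1), np.ones((1, 1, n), dtype=bool), bin_width)
    counts = np.bincount(disc.flat_levels, minlength=disc.ng + 1)[1:]
    p = counts[counts > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))

    if np.ptp(x) > 0:
        centered = x - mean
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2)  # not excess-corrected
    else:
        skew = float("nan")
        kurt = float("nan")

    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3) * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
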