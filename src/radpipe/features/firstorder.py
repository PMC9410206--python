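"""First-order (intensity histogram) features.

Computed on the raw masked intensities, except Entropy and Uniformity
which are defined on the fixed-bin-width discretized histogram.  Moments
use the population (biased) estimators; Kurtosis is not excess-corrected.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi

__all__ = ["firstorder_features", "FIRSTORDER_FEATURES"]

FIRSTORDER_FEATURES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def firstorder_features(
    values: np.ndarray, roi: DiscretizedRoi, voxel_volume: float
) -> dict[str, float]:
    """Compute the 18 default first-order features.

    Parameters
    ----------
    values : masked raw intensities (1D).
    roi : the fixed-bin-width discretization (for Entropy/Uniformity).
    voxel_volume : single-voxel volume in mm^3 (for TotalEnergy).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty intensity array")
    mean = float(x.mean())
    centred = x - mean
    m2 = float(np.mean(centred**2))
    m3 = float(np.mean(centred**3))
    m4 = float(np.mean(centred**4))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    bins = roi.masked_bins
    hist = np.bincount(bins)[1:].astype(float)
    p = hist[hist > 0] / n

    energy = float(np.sum(x**2))
    out = {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centred))),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean()))
        )
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "TotalEnergy": float(voxel_volume * energy),
        "Uniformity": float(np.sum(p**2)),
        "Variance": m2,
    }
    return {f"original_firstorder_{k}": v for k, v in out.items()}
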