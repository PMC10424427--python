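"""First-order (intensity histogram) features.

Computed on the raw HU values inside the region.  Entropy and Uniformity use
a fixed-bin-width discretisation (default 25 HU) so they match the texture
discretisation; all other features use the continuous values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .registry import FIRSTORDER_FEATURES


def _bin_probabilities(values: np.ndarray, bin_width: float) -> np.ndarray:
    edges_lo = np.floor(values.min() / bin_width) * bin_width
    nbins = int(np.floor((values.max() - edges_lo) / bin_width)) + 1
    counts = np.bincount(
        np.floor((values - edges_lo) / bin_width).astype(int), minlength=nbins
    )
    p = counts / counts.sum()
    return p[p > 0]


def firstorder_features(
    values: np.ndarray,
    voxel_volume_mm3: float,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """All 18 first-order features for one region's HU values."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty value array")
    p = _bin_probabilities(x, bin_width)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    mean = float(x.mean())
    n = x.size
    feats = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        # population moments; kurtosis is non-excess (3 for a Gaussian)
        "Skewness": float(stats.skew(x, bias=True)) if n > 1 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, bias=True, fisher=False)) if n > 1 else 0.0,
        "Variance": float(x.var()),
        "Uniformity": float((p**2).sum()),
    }
    assert set(feats) == set(FIRSTORDER_FEATURES)
    return feats
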