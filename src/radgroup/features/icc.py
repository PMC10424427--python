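"""Intraclass correlation and the reproducibility filter.

Features are screened by comparing the values extracted from two independent
segmentations of the same lesions.  The default agreement statistic is
ICC(2,1): a two-way random-effects, absolute-agreement, single-measurement
intraclass correlation computed from the two-way ANOVA mean squares.
Features with ICC below the threshold (default 0.75) are rejected; a feature
at exactly the threshold is retained, since the rejection rule is strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .extract import FeatureTable

ICC_UNDEFINED = np.nan


@dataclass
class IccFilterConfig:
    threshold: float = 0.75
    icc_form: str = "ICC2_1"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.icc_form != "ICC2_1":
            raise ValueError(f"unsupported ICC form: {self.icc_form}")


def icc_two_way(ratings: np.ndarray) -> float:
    """ICC(2,1) for an ``n_subjects × k_raters`` matrix (here k = 2).

    May be negative; returns NaN (flagged undefined) when the ratings have no
    variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be n_subjects × k_raters with k >= 2")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        return ICC_UNDEFINED

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICC_UNDEFINED
    return float((msr - mse) / denom)


def icc_per_feature(
    table_primary: FeatureTable, table_secondary: FeatureTable
) -> dict:
    """ICC(2,1) per shared FeatureKey over the overlapping lesion subset."""
    shared_rows = [
        lid for lid in table_primary.lesion_ids if lid in set(table_secondary.lesion_ids)
    ]
    if not shared_rows:
        raise ValueError("no overlapping subjects between the two tables")
    keys_a = table_primary.keys()
    keys_b = set(table_secondary.keys())
    shared_keys = [k for k in keys_a if k in keys_b]
    a = table_primary.subset(shared_keys).subset_rows(shared_rows).values
    b = table_secondary.subset(shared_keys).subset_rows(shared_rows).values
    return {
        key: icc_two_way(np.column_stack([a[:, j], b[:, j]]))
        for j, key in enumerate(shared_keys)
    }


def filter_reproducible(
    table_primary: FeatureTable,
    table_secondary: FeatureTable,
    config: IccFilterConfig | None = None,
) -> FeatureTable:
    """Drop features whose inter-segmentation ICC is below the threshold.

    Applied per FeatureKey (hence per ROI independently); undefined ICCs
    (zero-variance features) are rejected with a warning.
    """
    config = config or IccFilterConfig()
    iccs = icc_per_feature(table_primary, table_secondary)
    kept = [k for k, v in iccs.items() if np.isfinite(v) and v >= config.threshold]
    n_undef = sum(1 for v in iccs.values() if not np.isfinite(v))
    if n_undef:
        warnings.warn(f"{n_undef} features had undefined ICC and were rejected", stacklevel=2)
    if not kept:
        raise ValueError("no features survived the ICC filter")
    return table_primary.subset(kept)
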