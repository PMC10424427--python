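"""Feature tables and per-lesion extraction.

A :class:`FeatureTable` is a lesions × features matrix whose columns are
:class:`~radgroup.features.registry.FeatureKey` annotated (ROI, class, name)
triples, backed by a pandas DataFrame with a 3-level column MultiIndex.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imaging import BinaryMask, ImageVolume, RoiSet
from .firstorder import firstorder_features
from .registry import FEATURE_CLASSES, FeatureKey, feature_names
from .shape import shape_features
from .texture import texture_features

_COL_NAMES = ["roi", "feature_class", "feature_name"]


@dataclass
class ExtractionConfig:
    """Deterministic extraction settings, hashed into table metadata."""

    bin_width_hu: float = 25.0
    min_pixels_per_slice: int = 5
    texture_aggregation: str = "slice_mean"

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class FeatureTable:
    """Lesions × annotated radiomics features."""

    def __init__(self, data: pd.DataFrame, metadata: dict | None = None):
        if data.columns.nlevels != 3:
            raise ValueError("FeatureTable requires (roi, class, name) columns")
        if data.columns.duplicated().any():
            raise ValueError("duplicate FeatureKeys in table")
        data = data.copy()
        data.columns = data.columns.set_names(_COL_NAMES)
        self.data = data.astype(float)
        self.metadata = dict(metadata or {})

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: dict[str, dict[FeatureKey, float]],
        metadata: dict | None = None,
    ) -> "FeatureTable":
        """Build from {lesion_id: {FeatureKey: value}}."""
        frames = {}
        for lesion, feats in records.items():
            frames[lesion] = pd.Series(
                {(k.roi, k.feature_class, k.feature_name): v for k, v in feats.items()}
            )
        df = pd.DataFrame(frames).T
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=_COL_NAMES)
        return cls(df, metadata)

    # -- accessors --------------------------------------------------------
    @property
    def lesion_ids(self) -> list[str]:
        return list(self.data.index)

    def keys(self) -> list[FeatureKey]:
        return [FeatureKey(*col) for col in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, keys: list[FeatureKey]) -> "FeatureTable":
        cols = [(k.roi, k.feature_class, k.feature_name) for k in keys]
        return FeatureTable(self.data.loc[:, cols], self.metadata)

    def subset_rows(self, lesion_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(lesion_ids)], self.metadata)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for k in self.keys():
            counts[k.feature_class] += 1
        return counts

    def concat_rows(self, other: "FeatureTable") -> "FeatureTable":
        return FeatureTable(pd.concat([self.data, other.data]), self.metadata)

    # -- serialization ----------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(_COL_NAMES, future_stack=True).rename("value").reset_index()
        long = long.rename(columns={"level_0": "lesion_id", "index": "lesion_id"})
        long.columns = ["lesion_id", "roi", "feature_class", "feature_name", "value"]
        return long

    def to_csv(self, path: str) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, metadata: dict | None = None) -> "FeatureTable":
        long = pd.read_csv(path)
        wide = long.pivot_table(
            index="lesion_id",
            columns=["roi", "feature_class", "feature_name"],
            values="value",
            sort=False,
        )
        return cls(wide, metadata)


# ---------------------------------------------------------------------------


def extract_region_features(
    image: ImageVolume,
    mask: BinaryMask,
    roi_label: str,
    config: ExtractionConfig | None = None,
) -> dict[FeatureKey, float]:
    """Extract shape + first-order + 2D texture features for one region."""
    config = config or ExtractionConfig()
    voxel_volume = float(np.prod(mask.spacing))
    out: dict[FeatureKey, float] = {}
    for name, val in shape_features(mask).items():
        out[FeatureKey(roi_label, "shape", name)] = val
    fo = firstorder_features(
        image.values[mask.values], voxel_volume, bin_width=config.bin_width_hu
    )
    for name, val in fo.items():
        out[FeatureKey(roi_label, "firstorder", name)] = val
    tx = texture_features(
        image,
        mask,
        bin_width=config.bin_width_hu,
        min_pixels_per_slice=config.min_pixels_per_slice,
    )
    for name, val in tx.items():
        out[FeatureKey(roi_label, "texture", name)] = val
    return out


def extract_feature_table(
    image: ImageVolume,
    roi_set: RoiSet,
    config: ExtractionConfig | None = None,
    lesion_id: str = "lesion",
) -> FeatureTable:
    """One-row FeatureTable for a lesion over all regions of an ROI set.

    Regions flagged empty on the RoiSet make the lesion ineligible for this
    ROI set, so an empty (0-row) table is returned with the flags recorded in
    metadata — the caller drops the lesion rather than imputing.
    """
    config = config or ExtractionConfig()
    meta = {
        "roi_set": roi_set.name,
        "config_hash": config.config_hash(),
        "flags": list(roi_set.flags),
    }
    if roi_set.flags:
        empty = pd.DataFrame(
            index=pd.Index([], name="lesion_id"),
            columns=pd.MultiIndex.from_tuples(
                [
                    (roi, fc, name)
                    for roi in roi_set.region_labels
                    for fc in FEATURE_CLASSES
                    for name in feature_names(fc)
                ],
                names=_COL_NAMES,
            ),
        )
        return FeatureTable(empty, meta)
    feats: dict[FeatureKey, float] = {}
    for roi_label, mask in roi_set.masks.items():
        feats.update(extract_region_features(image, mask, roi_label, config))
    return FeatureTable.from_records({lesion_id: feats}, meta)
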