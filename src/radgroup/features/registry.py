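"""Feature naming and grouping registry.

Every extracted feature is identified by a :class:`FeatureKey` carrying the
ROI label, its feature class (``shape`` / ``firstorder`` / ``texture``) and
its name.  The registry is a partition: each feature name maps to exactly one
class, and exactly one shape feature per ROI is the mesh volume.

The default roster is 14 shape, 18 first-order and 73 texture features
(22 co-occurrence, 16 run-length, 16 size-zone, 14 dependence and 5
neighbourhood grey-tone difference features, all computed slice-wise in 2D).
"""

from __future__ import annotations

from dataclasses import dataclass

FEATURE_CLASSES = ("shape", "firstorder", "texture")

MESH_VOLUME_NAME = "MeshVolume"

SHAPE_FEATURES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_FEATURES = (
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

GLCM_FEATURES = (
    "glcm_Autocorrelation",
    "glcm_JointAverage",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_InverseVariance",
    "glcm_MaximumProbability",
    "glcm_SumEntropy",
    "glcm_SumSquares",
)

GLRLM_FEATURES = (
    "glrlm_ShortRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_GrayLevelVariance",
    "glrlm_RunVariance",
    "glrlm_RunEntropy",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_ZonePercentage",
    "glszm_GrayLevelVariance",
    "glszm_ZoneVariance",
    "glszm_ZoneEntropy",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "gldm_SmallDependenceEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_GrayLevelNonUniformity",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_GrayLevelVariance",
    "gldm_DependenceVariance",
    "gldm_DependenceEntropy",
    "gldm_LowGrayLevelEmphasis",
    "gldm_HighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = (
    "ngtdm_Coarseness",
    "ngtdm_Contrast",
    "ngtdm_Busyness",
    "ngtdm_Complexity",
    "ngtdm_Strength",
)

TEXTURE_FEATURES = (
    GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + GLDM_FEATURES + NGTDM_FEATURES
)


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Identity of one feature: ROI region label, feature class, feature name."""

    roi: str
    feature_class: str
    feature_name: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class: {self.feature_class}")

    @property
    def is_mesh_volume(self) -> bool:
        return self.feature_class == "shape" and self.feature_name == MESH_VOLUME_NAME

    def __str__(self) -> str:  # stable id used in CSV headers and audit logs
        return f"{self.roi}|{self.feature_class}|{self.feature_name}"

    @classmethod
    def parse(cls, s: str) -> "FeatureKey":
        roi, fclass, fname = s.split("|", 2)
        return cls(roi, fclass, fname)


def feature_names(feature_class: str) -> tuple[str, ...]:
    """The default name roster for one feature class."""
    return {
        "shape": SHAPE_FEATURES,
        "firstorder": FIRSTORDER_FEATURES,
        "texture": TEXTURE_FEATURES,
    }[feature_class]


def default_registry(roi_labels: tuple[str, ...] = ("whole",)) -> list[FeatureKey]:
    """All FeatureKeys emitted by the default configuration for given ROIs."""
    keys = []
    for roi in roi_labels:
        for fclass in FEATURE_CLASSES:
            for name in feature_names(fclass):
                keys.append(FeatureKey(roi, fclass, name))
    return keys
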