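"""Feature naming scheme.

A feature name encodes the image filter, the feature family, the statistic
and the segment: ``{filter}_{family}_{statistic}`` with an ``_ctv`` suffix
for mesorectum features (tumour features carry no suffix).  Shape features
exist only on the original image since they depend on the contour, not on
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

FILTERS = (
    "original",
    "log-sigma-1",
    "log-sigma-2",
    "log-sigma-3",
    "wavelet-LLL",
    "wavelet-LLH",
    "wavelet-LHL",
    "wavelet-LHH",
    "wavelet-HLL",
    "wavelet-HLH",
    "wavelet-HHL",
    "wavelet-HHH",
)

SHAPE_STATS = (
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

FIRSTORDER_STATS = (
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

GLCM_STATS = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_STATS = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_STATS = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_STATS = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

GLDM_STATS = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

FAMILY_STATS: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_STATS,
    "firstorder": FIRSTORDER_STATS,
    "glcm": GLCM_STATS,
    "glrlm": GLRLM_STATS,
    "glszm": GLSZM_STATS,
    "ngtdm": NGTDM_STATS,
    "gldm": GLDM_STATS,
}

#: intensity/texture statistics per filtered image (everything but shape)
N_INTENSITY_STATS = sum(
    len(v) for k, v in FAMILY_STATS.items() if k != "shape"
)  # 93
#: total per segmentation: 14 shape + 93 x 12 image types = 1130
N_FEATURES_PER_SEGMENT = len(SHAPE_STATS) + N_INTENSITY_STATS * len(FILTERS)


@dataclass(frozen=True)
class FeatureName:
    filter: str
    family: str
    statistic: str
    segment_suffix: str = ""

    def __post_init__(self) -> None:
        if self.filter not in FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}")
        if self.family not in FAMILY_STATS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "shape" and self.filter != "original":
            raise ValueError("shape features exist only on the original image")
        if self.segment_suffix not in ("", "_ctv"):
            raise ValueError(f"bad segment suffix {self.segment_suffix!r}")

    def __str__(self) -> str:
        return f"{self.filter}_{self.family}_{self.statistic}{self.segment_suffix}"


def feature_names(segment_suffix: str = "", filters=FILTERS) -> list[str]:
    """Serialized names in deterministic order: shape first, then per filter
    per family per statistic."""
    names = [
        str(FeatureName("original", "shape", s, segment_suffix))
        for s in SHAPE_STATS
    ]
    for filt in filters:
        for family in ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            for stat in FAMILY_STATS[family]:
                names.append(str(FeatureName(filt, family, stat, segment_suffix)))
    return names
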