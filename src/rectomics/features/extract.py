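"""Whole-subject feature extraction.

Per segmentation: 14 shape descriptors on the morphological mask plus 93
intensity/texture statistics on each of the 12 filtered images = 1130
features; tumour (GTV) and mesorectum (CTV) together give 2260, with CTV
names suffixed ``_ctv``.  Intensity statistics always use the *intensity*
mask (air removed against the original HU image); shape always uses the
*morphological* mask.  Images are assumed already resampled to an
isotropic grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volumes import SegmentationMask, VolumeGrid, intensity_resegment
from .filters import filter_bank
from .firstorder import firstorder_features
from .names import FILTERS, FeatureName, feature_names
from .shape import shape_features
from .texture import FAMILY_FUNCS, texture_features


@dataclass
class ExtractionConfig:
    bin_width: float = 10.0
    hu_floor: float = -50.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "coif1"
    gldm_alpha: float = 0.0
    filters: tuple[str, ...] = FILTERS  # restrict to e.g. ("original",)


def _bbox(mask: np.ndarray, margin: int = 1) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def extract_segment(
    volume: VolumeGrid,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
    suffix: str = "",
    context: str = "",
) -> dict[str, float]:
    """All features for one segmentation on one (resampled) volume."""
    config = config or ExtractionConfig()
    if mask.kind != "morphological":
        raise ValueError("extraction starts from the morphological mask")
    imask = intensity_resegment(mask, volume, config.hu_floor, context=context)

    out: dict[str, float] = {}
    for stat, val in shape_features(mask.values, mask.spacing_mm).items():
        out[str(FeatureName("original", "shape", stat, suffix))] = val

    box = _bbox(imask.values)
    voxel_vol = float(np.prod(volume.spacing_mm))
    images = filter_bank(
        volume.values, volume.spacing_mm, config.log_sigmas_mm, config.wavelet
    )
    m = imask.values[box]
    for filt in config.filters:
        img = images[filt][box]
        fo = firstorder_features(img, m, config.bin_width, voxel_vol)
        for stat, val in fo.items():
            out[str(FeatureName(filt, "firstorder", stat, suffix))] = val
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            if family == "gldm":
                from .discretize import discretize

                labels = discretize(img, m, config.bin_width, warn_bin_count=False)
                stats = FAMILY_FUNCS["gldm"](labels, config.gldm_alpha)
            else:
                stats = texture_features(img, m, config.bin_width, family)
            for stat, val in stats.items():
                out[str(FeatureName(filt, family, stat, suffix))] = val
    return out


def extract_all(
    volume: VolumeGrid,
    gtv: SegmentationMask,
    ctv: SegmentationMask,
    config: ExtractionConfig | None = None,
    subject_id: str = "",
) -> dict[str, float]:
    """2260-entry feature map for one subject (1130 per segment)."""
    config = config or ExtractionConfig()
    out = extract_segment(volume, gtv, config, suffix="", context=f"{subject_id} GTV")
    out.update(
        extract_segment(volume, ctv, config, suffix="_ctv", context=f"{subject_id} CTV")
    )
    return out


def extract_table(
    cases: list[tuple[str, VolumeGrid, SegmentationMask, SegmentationMask]],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Feature table: one row per subject, serialized feature-name columns."""
    rows = {
        sid: extract_all(vol, gtv, ctv, config, subject_id=sid)
        for sid, vol, gtv, ctv in cases
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    cfg = config or ExtractionConfig()
    expected = feature_names("", cfg.filters) + feature_names("_ctv", cfg.filters)
    return df[expected]
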