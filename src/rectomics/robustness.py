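"""Perturbation-based feature robustness screening.

Contouring variability is emulated with four morphological contour
variants (erode/dilate by 1 and 2 mm); scanner variability with fifteen
noise-injected images (Gaussian, Poisson and Uniform additive noise, five
replicates each, all with mean 20 HU and — for Gaussian and Uniform — SD
20 HU).  Features are re-extracted on every variant and kept only when
their intraclass correlation across variants reaches the threshold
(default 0.7) for both the contour set and the noise set.  Shape features
cannot respond to intensity noise on a fixed contour, so they are exempt
from the noise criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import HU_MAX, HU_MIN, SegmentationMask, VolumeGrid, morph_perturb

NOISE_MEAN_HU = 20.0
NOISE_SD_HU = 20.0
NOISE_DISTRIBUTIONS = ("gaussian", "poisson", "uniform")
N_NOISE_REPLICATES = 5
CONTOUR_VARIANT_SPECS = (
    ("erode", 1.0),
    ("erode", 2.0),
    ("dilate", 1.0),
    ("dilate", 2.0),
)


def contour_variants(mask: SegmentationMask) -> dict[str, SegmentationMask]:
    """The four contour variants: erode 1/2 mm, dilate 1/2 mm.

    An erosion that would empty the mask is skipped with a warning; the
    ICC over contour variants is then computed on the survivors.
    """
    out: dict[str, SegmentationMask] = {}
    for direction, radius in CONTOUR_VARIANT_SPECS:
        name = f"{direction}{radius:g}mm"
        try:
            out[name] = morph_perturb(mask, radius, direction)
        except ValueError as exc:
            warnings.warn(f"contour variant {name} skipped: {exc}", stacklevel=2)
    return out


def _noise_field(rng: np.random.Generator, dist: str, shape) -> np.ndarray:
    if dist == "gaussian":
        return rng.normal(NOISE_MEAN_HU, NOISE_SD_HU, size=shape)
    if dist == "poisson":
        # mean 20 implies variance 20 (SD ~4.47 HU)
        return rng.poisson(NOISE_MEAN_HU, size=shape).astype(np.float64)
    if dist == "uniform":
        half = NOISE_SD_HU * np.sqrt(3.0)
        return rng.uniform(NOISE_MEAN_HU - half, NOISE_MEAN_HU + half, size=shape)
    raise ValueError(f"unknown noise distribution {dist!r}")


def noise_variants(volume: VolumeGrid, seed: int) -> dict[str, VolumeGrid]:
    """Fifteen noise-injected volumes (3 distributions x 5 replicates).

    Noise is additive, voxelwise independent; the result is clipped to the
    valid scanner range [-1024, 3071] HU.  Replicate streams are spawned
    from the master seed, so the whole set is reproducible.
    """
    out: dict[str, VolumeGrid] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(NOISE_DISTRIBUTIONS) * N_NOISE_REPLICATES)
    k = 0
    for dist in NOISE_DISTRIBUTIONS:
        for rep in range(1, N_NOISE_REPLICATES + 1):
            rng = np.random.default_rng(children[k])
            k += 1
            noisy = volume.values + _noise_field(rng, dist, volume.shape)
            out[f"{dist}{rep}"] = volume.copy_with(np.clip(noisy, HU_MIN, HU_MAX))
    return out


# ---------------------------------------------------------------------------
# ICC


def icc_single_rater(values: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC(2,1).

    ``values``: subjects x variants, no missing cells.

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the rows/columns/error mean squares.  A table with
    zero total variance means identical measurements: ICC = 1.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 variants")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC table has missing cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return 1.0 if np.isclose(msr, mse) else 0.0
    return float((msr - mse) / denom)


def icc_table(tables: list[pd.DataFrame]) -> pd.Series:
    """ICC(2,1) per feature across variant tables (each subjects x features)."""
    stack = np.stack([t.to_numpy(dtype=np.float64) for t in tables], axis=-1)
    iccs = [icc_single_rater(stack[:, j, :]) for j in range(stack.shape[1])]
    return pd.Series(iccs, index=tables[0].columns, name="icc")


@dataclass
class ICCReport:
    table: pd.DataFrame  # columns: icc_contour, icc_noise, kept
    threshold: float
    mode: str = "separate"

    @property
    def robust_features(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def select_robust(
    original: pd.DataFrame,
    contour_tables: list[pd.DataFrame],
    noise_tables: list[pd.DataFrame],
    threshold: float = 0.7,
    mode: str = "separate",
) -> ICCReport:
    """Keep features robust to both contour and noise perturbation.

    ``mode='separate'`` (default): contour-ICC over {original + contour
    variants} and noise-ICC over {original + noise variants} must both
    reach the threshold.  ``mode='pooled'``: one ICC over all 20 tables.
    Shape features are exempt from the noise criterion.
    """
    cols = list(original.columns)
    for t in contour_tables + noise_tables:
        if list(t.columns) != cols or not t.index.equals(original.index):
            raise ValueError("variant tables must share subjects and columns")
    is_shape = pd.Series(
        ["_shape_" in c for c in cols], index=cols, dtype=bool
    )
    icc_contour = icc_table([original] + contour_tables)
    icc_noise = icc_table([original] + noise_tables)
    # a fixed contour under pure intensity noise leaves shape untouched
    icc_noise[is_shape] = 1.0

    if mode == "separate":
        kept = (icc_contour >= threshold) & (icc_noise >= threshold)
    elif mode == "pooled":
        pooled = icc_table([original] + contour_tables + noise_tables)
        kept = pooled >= threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")

    report = ICCReport(
        table=pd.DataFrame(
            {"icc_contour": icc_contour, "icc_noise": icc_noise, "kept": kept}
        ),
        threshold=threshold,
        mode=mode,
    )
    if not kept.any():
        raise ValueError(
            "no feature passed the ICC screen; consider reviewing the "
            f"threshold ({threshold})"
        )
    return report
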