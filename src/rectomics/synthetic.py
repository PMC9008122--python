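"""Synthetic phantom cohort generator.

Emulates the study material end to end with no external data: per subject
a CT-like volume holding a textured ellipsoidal tumour (GTV) inside a
mesorectal shell (CTV, disjoint from the GTV), an air lumen crossing the
tumour contour, and soft-tissue background; plus a clinical table with
staging, CEA (log-normal, partially missing), pathology drawn from
ordinal models, the NAR score and four censored time-to-event endpoints.

A latent "aggressiveness" a ~ N(0,1) drives both the tumour texture
(correlation length and variance of a Gaussian random field) and the
outcome hazards, so a combined image + clinical model genuinely has more
signal than a clinical model alone — a planted, recoverable truth.

Two tiers are provided:

* :func:`generate_cohort` — full images + masks + table (small n; feeds
  the extraction and robustness stages);
* :func:`generate_feature_cohort` — a radiomics-like feature matrix with
  one planted texture feature per segment plus correlated noise features
  (any n; feeds the modelling and evaluation stages directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .survival import ENDPOINTS, nar_classes, nar_score
from .volumes import SegmentationMask, VolumeGrid

__all__ = [
    "ClinicalEffects",
    "PhantomConfig",
    "generate_cohort",
    "generate_feature_cohort",
    "impute_cea",
    "PLANTED_CTV_FEATURE",
    "PLANTED_GTV_FEATURE",
]

#: names of the planted features in the tabular tier
PLANTED_CTV_FEATURE = "original_glcm_Contrast_ctv"
PLANTED_GTV_FEATURE = "original_glszm_GrayLevelVariance"


@dataclass
class ClinicalEffects:
    """Log-hazard coefficients of the clinical drivers of outcome."""

    cT: float = 0.30        # per stage above cT3
    pN: float = 0.50        # per nodal stage
    margin_positive: float = 0.60

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return (
            self.cT * (df["cT"].to_numpy(float) - 3.0)
            + self.pN * df["pN"].to_numpy(float)
            + self.margin_positive * (df["margin"] == "positive").to_numpy(float)
        )


@dataclass
class PhantomConfig:
    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (56, 56, 40)
    spacing_mm: tuple[float, float, float] = (1.25, 1.25, 2.5)  # profile A; B gets 2.0
    scanner_mix: float = 150 / 191  # fraction on profile A (2.5 mm slices)
    tumour_radius_mm: tuple[float, float] = (8.0, 14.0)
    shell_thickness_mm: tuple[float, float] = (5.0, 9.0)
    lumen_radius_mm: tuple[float, float] = (3.0, 5.0)
    texture_effect: float = 0.7  # beta_tex on the latent aggressiveness
    clinical_effects: ClinicalEffects = field(default_factory=ClinicalEffects)
    baseline_hazard: float = 0.004  # events per month at lp = 0
    admin_censor_months: float = 84.0
    cea_missing_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.scanner_mix <= 1.0:
            raise ValueError("scanner_mix must lie in [0, 1]")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        for name in ("tumour_radius_mm", "shell_thickness_mm", "lumen_radius_mm"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")


# ---------------------------------------------------------------------------
# clinical table

# marginal stage frequencies of the emulated population
_CT_PROBS = {2: 11 / 191, 3: 141 / 191, 4: 39 / 191}
_CN_PROBS = {0: 43 / 191, 1: 110 / 191, 2: 38 / 191}
# proportional-odds cutpoints for pT (marginals ~ 14/6/18/52/10 %) and pN
_PT_CUTS = np.array([-1.815, -1.386, -0.490, 2.197])
_PN_CUTS = np.array([0.447, 2.586])
# loading of the latent aggressiveness on the pathology ordinals: pT kept
# moderate so the coarse pathology covariates do not exhaust the
# texture-borne hazard signal; pN loaded strongly because the NAR score
# weights nodal stage heavily and the binary NAR endpoints must carry a
# recoverable texture signal
_PT_A_LOADING = 0.45
_PN_A_LOADING = 0.80
# CEA log-normal matched to median 5.9 ng/mL, IQR 2.7-16.0
_CEA_MU = float(np.log(5.9))
_CEA_SIGMA = 1.32


def _ordinal_draw(eta: np.ndarray, cuts: np.ndarray, rng) -> np.ndarray:
    """Proportional-odds draw: P(Y <= j) = sigmoid(cut_j - eta)."""
    u = rng.uniform(size=len(eta))
    cum = 1.0 / (1.0 + np.exp(-(cuts[None, :] - eta[:, None])))
    return (u[:, None] > cum).sum(axis=1)


def _clinical_table(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    a = rng.standard_normal(n)  # latent aggressiveness
    cT = rng.choice(list(_CT_PROBS), p=list(_CT_PROBS.values()), size=n)
    cN = rng.choice(list(_CN_PROBS), p=list(_CN_PROBS.values()), size=n)
    age = np.clip(rng.normal(63.0, 11.5, size=n), 28, 85).round(0)
    cea = np.exp(rng.normal(_CEA_MU, _CEA_SIGMA, size=n)).round(1)
    missing = rng.uniform(size=n) < config.cea_missing_fraction
    cea = np.where(missing, np.nan, cea)
    chemo = np.where(rng.uniform(size=n) < 144 / 191, "yes", "no")
    margin = rng.choice(
        ["clear", "close", "positive"], p=[157 / 191, 8 / 191, 26 / 191], size=n
    )
    rt_to_surgery = np.exp(rng.normal(np.log(71.0), 0.30, size=n)).round(0)

    # pathology: downstaging structure — higher cT and higher a shift pT up
    pT = _ordinal_draw(0.9 * (cT - 3.0) + _PT_A_LOADING * a, _PT_CUTS, rng)
    pN = _ordinal_draw(0.5 * cN + _PN_A_LOADING * a - 0.5, _PN_CUTS, rng)

    nar = nar_score(cT, pT, pN)
    gt16, lt8 = nar_classes(nar)

    df = pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "cT": cT,
            "cN": cN,
            "cea": cea,
            "adjuvant_chemo": chemo,
            "margin": margin,
            "time_rt_surgery_days": rt_to_surgery,
            "pT": pT,
            "pN": pN,
            "nar": np.round(nar, 2),
            "nar_gt16": gt16,
            "nar_lt8": lt8,
            "latent_a": a,
        }
    )

    # exponential event times per endpoint; shared linear predictor,
    # endpoint-specific baseline multiplier (DFS events are the most
    # frequent, LRFFS the least)
    lp = config.texture_effect * a + config.clinical_effects.linear_predictor(df)
    mult = {"lrffs": 0.8, "dmfs": 1.0, "dfs": 1.2, "os": 0.9}
    censor = np.minimum(
        rng.uniform(36.0, config.admin_censor_months, size=n),
        config.admin_censor_months,
    )
    for ep in ENDPOINTS:
        rate = config.baseline_hazard * mult[ep] * np.exp(lp)
        t = rng.exponential(1.0 / rate)
        df[f"{ep}_months"] = np.round(np.minimum(t, censor), 2)
        df[f"{ep}_event"] = (t <= censor).astype(int)
        df[f"{ep}_months"] = df[f"{ep}_months"].clip(lower=0.01)
    df["scanner"] = np.where(
        rng.uniform(size=n) < config.scanner_mix, "A", "B"
    )
    return df


# ---------------------------------------------------------------------------
# phantom images


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    axes = [np.arange(s) * sp for s, sp in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return (
        ((gx - center_mm[0]) / semi_mm[0]) ** 2
        + ((gy - center_mm[1]) / semi_mm[1]) ** 2
        + ((gz - center_mm[2]) / semi_mm[2]) ** 2
    ) <= 1.0


def _random_field(
    rng, shape, spacing, corr_mm: float, sd: float
) -> np.ndarray:
    """Gaussian random field: white noise smoothed to a correlation length
    (in mm) and rescaled to the target standard deviation."""
    w = rng.standard_normal(shape)
    sigma_vox = [max(corr_mm / s, 1e-3) for s in spacing]
    f = ndimage.gaussian_filter(w, sigma=sigma_vox)
    f_sd = f.std()
    return f * (sd / f_sd) if f_sd > 0 else f


def _phantom_image(
    config: PhantomConfig, rng: np.random.Generator, a: float, scanner: str
):
    spacing = (
        config.spacing_mm
        if scanner == "A"
        else (config.spacing_mm[0], config.spacing_mm[1], 2.0)
    )
    shape = config.grid_shape
    extent = [s * sp for s, sp in zip(shape, spacing)]
    center = [e / 2 for e in extent]

    r_lo, r_hi = config.tumour_radius_mm
    semi = rng.uniform(r_lo, r_hi, size=3)
    th = rng.uniform(*config.shell_thickness_mm)
    if any(c < semi.max() + th + 6.0 for c in center):
        raise ValueError(
            "grid too small to contain the mesorectal shell plus margin; "
            "increase grid_shape or shrink the tumour/shell ranges"
        )

    gtv = _ellipsoid(shape, spacing, center, semi)
    outer = _ellipsoid(shape, spacing, center, semi + th)
    gap = _ellipsoid(shape, spacing, center, semi + 1.0)
    ctv = outer & ~gap  # one-voxel-scale moat keeps GTV and CTV disjoint

    # image: soft-tissue background, textured tumour, air lumen
    img = 45.0 + _random_field(rng, shape, spacing, corr_mm=3.0, sd=6.0)
    corr = 1.5 * float(np.exp(0.25 * a))
    sd = 25.0 * float(np.exp(0.15 * a))
    texture = _random_field(rng, shape, spacing, corr_mm=corr, sd=sd)
    img[gtv] = 40.0 + texture[gtv]
    img[ctv] += _random_field(rng, shape, spacing, corr_mm=2.0, sd=8.0)[ctv]

    # lumen cylinder along z, offset so it crosses the GTV boundary
    lr = rng.uniform(*config.lumen_radius_mm)
    axes = [np.arange(s) * sp for s, sp in zip(shape[:2], spacing[:2])]
    gx, gy = np.meshgrid(*axes, indexing="ij")
    lumen_center = (center[0] + semi[0] - lr / 2.0, center[1])
    lumen2d = ((gx - lumen_center[0]) ** 2 + (gy - lumen_center[1]) ** 2) <= lr**2
    lumen = np.broadcast_to(lumen2d[:, :, None], shape).copy()
    img[lumen] = -1000.0

    # scanner noise: profile A is the noisier of the two
    noise_sd = 10.0 if scanner == "A" else 7.0
    img = img + rng.normal(0.0, noise_sd, size=shape)

    vol = VolumeGrid(img, spacing)
    gtv_mask = SegmentationMask(gtv, spacing, role="GTV")
    ctv_mask = SegmentationMask(ctv & ~lumen, spacing, role="CTV")
    return vol, gtv_mask, ctv_mask


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[tuple[VolumeGrid, SegmentationMask, SegmentationMask]], pd.DataFrame]:
    """Full phantom cohort: per-subject (volume, GTV, CTV) plus the table.

    Deterministic for a fixed ``config.seed``; image randomness and
    clinical randomness come from independent child streams.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_clin, rng_img = (np.random.default_rng(c) for c in ss.spawn(2))
    table = _clinical_table(config, rng_clin)
    cases = []
    for i in range(config.n_subjects):
        cases.append(
            _phantom_image(
                config, rng_img, float(table["latent_a"].iloc[i]), table["scanner"].iloc[i]
            )
        )
    return cases, table


# ---------------------------------------------------------------------------
# tabular tier


def generate_feature_cohort(
    config: PhantomConfig,
    n_radiomics: int = 30,
    planted_noise_sd: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Modelling-scale cohort: a radiomics-like feature matrix, no images.

    One CTV feature (:data:`PLANTED_CTV_FEATURE`) carries the latent
    aggressiveness ``a`` with additive noise; one GTV feature carries half
    the signal; the remaining columns are correlated Gaussian noise from a
    two-factor model (so Spearman pruning has real work to do).  Outcomes
    in the table depend on ``a`` exactly as in the image tier, so planted
    signal strength is governed by ``config.texture_effect``.
    """
    if n_radiomics < 4:
        raise ValueError("n_radiomics must be at least 4")
    ss = np.random.SeedSequence(config.seed)
    rng_clin, _, rng_feat = (np.random.default_rng(c) for c in ss.spawn(3))
    table = _clinical_table(config, rng_clin)
    n = config.n_subjects
    a = table["latent_a"].to_numpy()

    cols = {}
    cols[PLANTED_CTV_FEATURE] = a + planted_noise_sd * rng_feat.standard_normal(n)
    cols[PLANTED_GTV_FEATURE] = 0.5 * a + rng_feat.standard_normal(n)
    factors = rng_feat.standard_normal((n, 2))
    from .features.names import feature_names

    pool = [
        c
        for c in feature_names("") + feature_names("_ctv")
        if "_shape_" not in c and c not in cols
    ]
    step = max(1, len(pool) // (n_radiomics - 2))
    picked = pool[:: step][: n_radiomics - 2]
    for j, name in enumerate(picked):
        load = rng_feat.uniform(-0.8, 0.8, size=2)
        cols[name] = factors @ load + rng_feat.standard_normal(n)
    X = pd.DataFrame(cols, index=table["id"])
    table = table.set_index("id", drop=False)
    return X, table


# ---------------------------------------------------------------------------
# CEA imputation


def impute_cea(records: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing CEA values; observed values are untouched."""
    out = records.copy()
    cea = out["cea"]
    if cea.notna().sum() == 0:
        raise ValueError("cannot impute CEA: all values are missing")
    out["cea"] = cea.fillna(cea.median())
    return out
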