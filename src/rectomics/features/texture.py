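"""Gray-level texture matrices in 3D.

Five families over the discretized in-mask gray levels:

* GLCM  — co-occurrence at distance 1 along the 13 unique 3D directions;
  symmetric and normalized; statistics computed per direction, then
  averaged.
* GLRLM — run lengths per direction, statistics averaged over directions.
* GLSZM — 26-connected iso-level zones (direction-free).
* NGTDM — neighbourhood gray-tone difference over the 26-neighbourhood.
* GLDM  — gray-level dependence counts over the 26-neighbourhood with
  dependence tolerance alpha (default 0: equal levels only); the
  dependence size includes the centre voxel, so it is always >= 1.

Gray levels absent from the region are dropped from the matrices but the
surviving levels keep their original integer values in the statistics
(low/high gray-level emphases weight by the actual label).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique direction offsets at Chebyshev distance 1 (one per +/- pair)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_EPS = np.finfo(np.float64).eps


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(labels: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts over present levels for one offset.

    ``labels``: integer array with 0 outside the mask.  Returns a dense
    matrix indexed by the sorted list of present levels (see
    :func:`present_levels`).
    """
    levels = present_levels(labels)
    lut = np.zeros(levels.max() + 1, dtype=np.int64)
    lut[levels] = np.arange(len(levels))
    a, b = _shifted_pairs(labels, direction)
    m = np.zeros((len(levels), len(levels)), dtype=np.float64)
    if a.size:
        np.add.at(m, (lut[a], lut[b]), 1.0)
    return m + m.T


def present_levels(labels: np.ndarray) -> np.ndarray:
    lv = np.unique(labels)
    return lv[lv > 0]


def _shifted_pairs(labels: np.ndarray, d: tuple[int, int, int]):
    """In-mask voxel pairs (level_a, level_b) at offset ``d``."""
    sl_a, sl_b = [], []
    for off, n in zip(d, labels.shape):
        if off == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif off > 0:
            sl_a.append(slice(0, n - off))
            sl_b.append(slice(off, n))
        else:
            sl_a.append(slice(-off, n))
            sl_b.append(slice(0, n + off))
    a = labels[tuple(sl_a)].ravel()
    b = labels[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def _glcm_stats(m: np.ndarray, levels: np.ndarray, n_levels_total: int) -> dict[str, float]:
    s = m.sum()
    if s == 0:
        # no co-occurring pair along this direction
        return {}
    p = m / s
    i = levels.astype(np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())
    ng = n_levels_total

    diff = np.abs(ii - jj)
    # difference distribution over k = |i - j|
    dk, dinv = np.unique(diff.ravel(), return_inverse=True)
    pdiff = np.bincount(dinv, weights=p.ravel())
    da = float((dk * pdiff).sum())
    # sum distribution over k = i + j
    sk, sinv = np.unique((ii + jj).ravel(), return_inverse=True)
    psum = np.bincount(sinv, weights=p.ravel())

    hx = _entropy2(px)
    hxy = _entropy2(p.ravel())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sigma2 > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        corr = 1.0  # zero-variance region: perfectly correlated by convention

    # MCC via second-largest eigenvalue of Q
    if len(i) > 1 and px.min() > 0:
        q = (p / px[:, None]) @ (p / px[None, :]).T
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real)))
    else:
        mcc = 1.0

    off = diff > 0
    inv_var = float((p[off] / diff[off] ** 2).sum()) if off.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float((diff**2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(pdiff),
        "DifferenceVariance": float(((dk - da) ** 2 * pdiff).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff**2)).sum()),
        "Idmn": float((p / (1.0 + (diff / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((sk * psum).sum()),
        "SumEntropy": _entropy2(psum),
        "SumSquares": sigma2,
    }


def glcm_features(labels: np.ndarray) -> dict[str, float]:
    levels = present_levels(labels)
    if levels.size == 0:
        raise ValueError("empty region")
    per_dir = []
    for d in DIRECTIONS:
        stats = _glcm_stats(glcm_matrix(labels, d), levels, len(levels))
        if stats:
            per_dir.append(stats)
    if not per_dir:
        raise ValueError("region has no voxel pairs in any direction")
    return {k: float(np.mean([s[k] for s in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(labels: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P[level_index, run_length - 1] for one direction."""
    levels = present_levels(labels)
    lut = np.zeros(levels.max() + 1, dtype=np.int64)
    lut[levels] = np.arange(len(levels))

    idx = np.argwhere(labels > 0)
    vals = labels[labels > 0]
    d = np.asarray(direction)
    # voxels on the same line share the key = position - t * d, with t the
    # coordinate along the first nonzero axis of d (that component is +1 by
    # construction of DIRECTIONS, so t increases along the direction)
    c = int(np.nonzero(d)[0][0])
    t = idx[:, c]
    key = idx - t[:, None] * d
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_s, v_s, k_s = t[order], vals[order], key[order]

    new_line = np.ones(len(t_s), dtype=bool)
    if len(t_s) > 1:
        same_key = (k_s[1:] == k_s[:-1]).all(axis=1)
        contiguous = t_s[1:] == t_s[:-1] + 1
        same_val = v_s[1:] == v_s[:-1]
        new_line[1:] = ~(same_key & contiguous & same_val)
    run_id = np.cumsum(new_line) - 1
    run_len = np.bincount(run_id)
    run_val = v_s[new_line]

    max_len = int(run_len.max())
    m = np.zeros((len(levels), max_len), dtype=np.float64)
    np.add.at(m, (lut[run_val], run_len - 1), 1.0)
    return m


def _length_family_stats(
    m: np.ndarray, levels: np.ndarray, n_voxels: int, prefix: str
) -> dict[str, float]:
    """Shared statistic set for run-length (prefix='Run') and size-zone
    (prefix='Area'/'Zone') matrices."""
    nr = m.sum()
    p = m / nr
    g = levels.astype(np.float64)
    l = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    gg, ll = np.meshgrid(g, l, indexing="ij")
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mug = float((pg * g).sum())
    mul = float((pl * l).sum())
    return {
        "short": float((p / ll**2).sum()),
        "long": float((p * ll**2).sum()),
        "gln": float((m.sum(axis=1) ** 2).sum() / nr),
        "glnn": float((m.sum(axis=1) ** 2).sum() / nr**2),
        "rln": float((m.sum(axis=0) ** 2).sum() / nr),
        "rlnn": float((m.sum(axis=0) ** 2).sum() / nr**2),
        "pct": float(nr / n_voxels),
        "glv": float((pg * (g - mug) ** 2).sum()),
        "lv": float((pl * (l - mul) ** 2).sum()),
        "entropy": _entropy2(p.ravel()),
        "lgl": float((p / gg**2).sum()),
        "hgl": float((p * gg**2).sum()),
        "sl": float((p / (gg**2 * ll**2)).sum()),
        "sh": float((p * gg**2 / ll**2).sum()),
        "ll": float((p * ll**2 / gg**2).sum()),
        "lh": float((p * gg**2 * ll**2).sum()),
    }


_GLRLM_KEYS = {
    "ShortRunEmphasis": "short",
    "LongRunEmphasis": "long",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "rln",
    "RunLengthNonUniformityNormalized": "rlnn",
    "RunPercentage": "pct",
    "GrayLevelVariance": "glv",
    "RunVariance": "lv",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "lgl",
    "HighGrayLevelRunEmphasis": "hgl",
    "ShortRunLowGrayLevelEmphasis": "sl",
    "ShortRunHighGrayLevelEmphasis": "sh",
    "LongRunLowGrayLevelEmphasis": "ll",
    "LongRunHighGrayLevelEmphasis": "lh",
}


def glrlm_features(labels: np.ndarray) -> dict[str, float]:
    levels = present_levels(labels)
    if levels.size == 0:
        raise ValueError("empty region")
    n_vox = int((labels > 0).sum())
    per_dir = []
    for d in DIRECTIONS:
        m = glrlm_matrix(labels, d)
        per_dir.append(_length_family_stats(m, levels, n_vox, "Run"))
    return {
        name: float(np.mean([s[key] for s in per_dir]))
        for name, key in _GLRLM_KEYS.items()
    }


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zone-size counts P[level_index, size - 1] with 26-connectivity."""
    levels = present_levels(labels)
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level: list[tuple[int, int]] = []
    for li, g in enumerate(levels):
        lab, n = ndimage.label(labels == g, structure=structure)
        if n:
            counts = np.bincount(lab.ravel())[1:]
            sizes_per_level.extend((li, int(c)) for c in counts)
    max_size = max(s for _, s in sizes_per_level)
    m = np.zeros((len(levels), max_size), dtype=np.float64)
    for li, s in sizes_per_level:
        m[li, s - 1] += 1.0
    return m, levels


_GLSZM_KEYS = {
    "SmallAreaEmphasis": "short",
    "LargeAreaEmphasis": "long",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "rln",
    "SizeZoneNonUniformityNormalized": "rlnn",
    "ZonePercentage": "pct",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "lv",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "sl",
    "SmallAreaHighGrayLevelEmphasis": "sh",
    "LargeAreaLowGrayLevelEmphasis": "ll",
    "LargeAreaHighGrayLevelEmphasis": "lh",
}


def glszm_features(labels: np.ndarray) -> dict[str, float]:
    m, levels = glszm_matrix(labels)
    n_vox = int((labels > 0).sum())
    stats = _length_family_stats(m, levels, n_vox, "Area")
    return {name: stats[key] for name, key in _GLSZM_KEYS.items()}


# ---------------------------------------------------------------------------
# 26-neighbourhood helpers


_NEIGH_KERNEL = np.ones((3, 3, 3), dtype=np.float64)
_NEIGH_KERNEL[1, 1, 1] = 0.0


def _neighbour_sums(labels: np.ndarray):
    """Per-voxel sum of in-mask neighbour levels and neighbour counts."""
    mask = (labels > 0).astype(np.float64)
    vals = labels.astype(np.float64) * mask
    nsum = ndimage.correlate(vals, _NEIGH_KERNEL, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(mask, _NEIGH_KERNEL, mode="constant", cval=0.0)
    return nsum, ncnt


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per present level: (level value, n_i voxels, s_i absolute-difference sum)."""
    levels = present_levels(labels)
    nsum, ncnt = _neighbour_sums(labels)
    mask = labels > 0
    valid = mask & (ncnt > 0)
    avg = np.zeros_like(nsum)
    avg[valid] = nsum[valid] / ncnt[valid]
    n_i = np.array([(labels[valid] == g).sum() for g in levels], dtype=np.float64)
    s_i = np.array(
        [np.abs(g - avg[valid & (labels == g)]).sum() for g in levels],
        dtype=np.float64,
    )
    return levels.astype(np.float64), n_i, s_i


def ngtdm_features(labels: np.ndarray) -> dict[str, float]:
    g, n_i, s_i = ngtdm_table(labels)
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("region has no voxel with an in-mask neighbour")
    p = n_i / nvp
    ngp = int((n_i > 0).sum())
    gi, gj = np.meshgrid(g, g, indexing="ij")
    pi, pj = np.meshgrid(p, p, indexing="ij")
    both = (pi > 0) & (pj > 0)

    coarse_den = float((p * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        contrast = float(
            (pi[both] * pj[both] * (gi[both] - gj[both]) ** 2).sum()
            / (ngp * (ngp - 1))
            * s_i.sum()
            / nvp
        )
    else:
        contrast = 0.0

    busy_den = float(np.abs(gi[both] * pi[both] - gj[both] * pj[both]).sum())
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0

    si_, sj_ = np.meshgrid(s_i, s_i, indexing="ij")
    complexity = float(
        (
            np.abs(gi[both] - gj[both])
            * (pi[both] * si_[both] + pj[both] * sj_[both])
            / (pi[both] + pj[both])
        ).sum()
        / nvp
    )

    s_sum = float(s_i.sum())
    strength = (
        float(((pi[both] + pj[both]) * (gi[both] - gj[both]) ** 2).sum()) / s_sum
        if s_sum > 0
        else 0.0
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(labels: np.ndarray, alpha: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Dependence counts P[level_index, dependence - 1].

    Dependence of a voxel = 1 + number of in-mask neighbours whose level
    differs by at most ``alpha`` (the centre always depends on itself).
    """
    levels = present_levels(labels)
    lut = np.zeros(levels.max() + 1, dtype=np.int64)
    lut[levels] = np.arange(len(levels))
    mask = labels > 0
    dep = np.ones(labels.shape, dtype=np.int64)
    for d in DIRECTIONS:
        a_idx, b_idx = _shifted_index_pairs(labels, d)
        # a neighbour contributes to both endpoints of the pair
        diffs = np.abs(labels.ravel()[a_idx] - labels.ravel()[b_idx]) <= alpha
        np.add.at(dep.ravel(), a_idx[diffs], 1)
        np.add.at(dep.ravel(), b_idx[diffs], 1)
    max_dep = int(dep[mask].max())
    m = np.zeros((len(levels), max_dep), dtype=np.float64)
    np.add.at(m, (lut[labels[mask]], dep[mask] - 1), 1.0)
    return m, levels


def _shifted_index_pairs(labels: np.ndarray, d: tuple[int, int, int]):
    """Flat indices of in-mask voxel pairs at offset ``d``."""
    flat = np.arange(labels.size).reshape(labels.shape)
    sl_a, sl_b = [], []
    for off, n in zip(d, labels.shape):
        if off == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif off > 0:
            sl_a.append(slice(0, n - off))
            sl_b.append(slice(off, n))
        else:
            sl_a.append(slice(-off, n))
            sl_b.append(slice(0, n + off))
    a = flat[tuple(sl_a)].ravel()
    b = flat[tuple(sl_b)].ravel()
    lv = labels.ravel()
    keep = (lv[a] > 0) & (lv[b] > 0)
    return a[keep], b[keep]


def gldm_features(labels: np.ndarray, alpha: float = 0.0) -> dict[str, float]:
    m, levels = gldm_matrix(labels, alpha)
    nz = m.sum()
    p = m / nz
    g = levels.astype(np.float64)
    j = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mug = float((pg * g).sum())
    muj = float((pj * j).sum())
    return {
        "SmallDependenceEmphasis": float((p / jj**2).sum()),
        "LargeDependenceEmphasis": float((p * jj**2).sum()),
        "GrayLevelNonUniformity": float((m.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((m.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((m.sum(axis=0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float((pg * (g - mug) ** 2).sum()),
        "DependenceVariance": float((pj * (j - muj) ** 2).sum()),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float((p / gg**2).sum()),
        "HighGrayLevelEmphasis": float((p * gg**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (gg**2 * jj**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * gg**2 / jj**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * jj**2 / gg**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * gg**2 * jj**2).sum()),
    }


FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def texture_features(
    values: np.ndarray, mask: np.ndarray, bin_width: float, family: str
) -> dict[str, float]:
    """Discretize then dispatch to one texture family."""
    from .discretize import discretize

    if family not in FAMILY_FUNCS:
        raise ValueError(f"unknown texture family {family!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("texture features require at least 2 in-mask voxels")
    labels = discretize(values, mask, bin_width, warn_bin_count=False)
    return FAMILY_FUNCS[family](labels)
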