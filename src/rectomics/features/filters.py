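"""Image filter bank: original, Laplacian-of-Gaussian, wavelet subbands.

LoG sigmas are specified in physical mm and converted to voxel units with
the grid spacing, so "sigma 2 mm" is the same physical bandpass on any
grid.  The wavelet decomposition is a single-level undecimated transform:
the 1D decomposition filters of a chosen wavelet (default coiflet-1) are
applied along each axis in every lowpass/highpass combination, yielding 8
subbands (LLL ... HHH) on the input lattice.  The lowpass filter is
normalized to unit DC gain so that the LLL band of a constant volume is
that constant.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage

WAVELET_SUBBANDS = tuple(
    "".join(c) for c in product("LH", repeat=3)
)  # LLL, LLH, ..., HHH

LOG_SIGMAS_MM = (1.0, 2.0, 3.0)


def log_filter(
    values: np.ndarray,
    sigma_mm: float,
    spacing_mm: tuple[float, float, float],
    truncate: float = 4.0,
) -> np.ndarray:
    """Laplacian of Gaussian with sigma in mm.

    Built from separable Gaussian / second-derivative-of-Gaussian kernels;
    the derivative kernel is re-centred to sum exactly to zero so a
    constant volume maps to exactly zero despite kernel truncation.
    """
    vol = values.astype(np.float64)
    kernels = []
    for s in spacing_mm:
        sig = sigma_mm / s
        r = max(1, int(truncate * sig + 0.5))
        x = np.arange(-r, r + 1, dtype=np.float64)
        g = np.exp(-(x**2) / (2 * sig**2))
        g /= g.sum()
        g2 = (x**2 / sig**4 - 1.0 / sig**2) * g
        g2 -= g2.sum() / g2.size
        kernels.append((g, g2))
    out = np.zeros_like(vol)
    for ax in range(3):
        t = vol
        for ax2 in range(3):
            k = kernels[ax2][1] if ax2 == ax else kernels[ax2][0]
            t = ndimage.convolve1d(t, k, axis=ax2, mode="reflect")
        out += t
    return out


def wavelet_subbands(
    values: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Undecimated single-level 3D wavelet subbands at input lattice size."""
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    lo = lo / lo.sum()  # unit DC gain
    hi = hi / np.abs(lo).sum() / np.sqrt(2)  # matched scale
    filters = {"L": lo, "H": hi}
    out: dict[str, np.ndarray] = {}
    for bands in WAVELET_SUBBANDS:
        img = values.astype(np.float64)
        for axis, b in enumerate(bands):
            img = ndimage.convolve1d(img, filters[b], axis=axis, mode="reflect")
        out[bands] = img
    return out


def filter_bank(
    values: np.ndarray,
    spacing_mm: tuple[float, float, float],
    sigmas_mm: tuple[float, ...] = LOG_SIGMAS_MM,
    wavelet: str = "coif1",
) -> dict[str, np.ndarray]:
    """The 12 images features are extracted from: original, LoG at each
    sigma, and the 8 wavelet subbands."""
    values = np.asarray(values, dtype=np.float64)
    min_side = min(values.shape)
    support = max(len(pywt.Wavelet(wavelet).dec_lo), 4)
    if min_side < support:
        raise ValueError(
            f"volume side {min_side} smaller than filter support {support}"
        )
    out = {"original": values}
    for s in sigmas_mm:
        out[f"log-sigma-{s:g}"] = log_filter(values, s, spacing_mm)
    for band, img in wavelet_subbands(values, wavelet).items():
        out[f"wavelet-{band}"] = img
    return out
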