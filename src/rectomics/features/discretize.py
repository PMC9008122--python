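"""Fixed-bin-width gray-level discretization.

Texture matrices are built on integer gray levels obtained by binning HU
values with a constant bin width (default 10 HU), anchored at the in-mask
minimum so that the first occupied bin is always labelled 1:

    bin(x) = floor(x / w) - floor(min / w) + 1

A constant bin width keeps the absolute HU contrast captured by one level
identical across subjects, which matters when intensities are calibrated
(as CT is).  The resulting bin count should land roughly between 16 and
128; a warning is emitted otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np

BIN_COUNT_RANGE = (16, 128)


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float = 10.0,
               warn_bin_count: bool = True) -> np.ndarray:
    """Return integer bin labels (>= 1) for the in-mask voxels of ``values``.

    Out-of-mask voxels get label 0.  ``mask`` must be non-empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty mask region")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray(values, dtype=np.float64)
    lo = vals[mask].min()
    labels = np.zeros(vals.shape, dtype=np.int64)
    labels[mask] = (
        np.floor(vals[mask] / bin_width) - np.floor(lo / bin_width) + 1
    ).astype(np.int64)
    n_bins = int(labels[mask].max())
    if warn_bin_count and not (BIN_COUNT_RANGE[0] <= n_bins <= BIN_COUNT_RANGE[1]):
        warnings.warn(
            f"discretization produced {n_bins} bins, outside the recommended "
            f"range {BIN_COUNT_RANGE}",
            stacklevel=2,
        )
    return labels
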