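"""Numba-compiled gather/scatter kernels for the convolution lowering.

NumPy's fancy indexing tops out around 10 ns/element, which dominates the
im2col lowering; these tight loops run close to copy bandwidth.  Pure-NumPy
fallbacks keep the package importable without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _gather(xf, idx, cols):  # pragma: no cover - compiled
    n_batch, n_ch, _ = xf.shape
    k = idx.size
    for n in range(n_batch):
        for c in range(n_ch):
            src = xf[n, c]
            dst = cols[n, c]
            for j in range(k):
                dst[j] = src[idx[j]]


@njit(cache=True)
def _scatter_add(dcols, idx, dxf):  # pragma: no cover - compiled
    n_batch, n_ch, _ = dxf.shape
    k = idx.size
    for n in range(n_batch):
        for c in range(n_ch):
            src = dcols[n, c]
            dst = dxf[n, c]
            for j in range(k):
                dst[idx[j]] += src[j]


def gather_cols(xf: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """cols[n, c, j] = xf[n, c, idx[j]] — the im2col lowering gather."""
    if HAVE_NUMBA:
        cols = np.empty(xf.shape[:2] + (idx.size,), dtype=xf.dtype)
        _gather(xf, idx, cols)
        return cols
    return xf[:, :, idx]


def scatter_add_cols(dcols: np.ndarray, idx: np.ndarray,
                     dxf: np.ndarray) -> None:
    """dxf[n, c, idx[j]] += dcols[n, c, j] — the col2im accumulation."""
    if HAVE_NUMBA:
        _scatter_add(dcols, idx, dxf)
    else:
        np.add.at(dxf, (slice(None), slice(None), idx), dcols)
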