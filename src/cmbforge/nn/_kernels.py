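"""JIT-compiled memory-movement kernels for the convolution layers.

The im2col unfold and its col2im adjoint are pure memory permutations with
a short contiguous inner axis; numba compiles them to tight loops that run
at memory bandwidth.  A NumPy fallback with identical semantics is used if
numba is unavailable, and the test suite asserts both paths agree.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        if a and callable(a[0]):
            return a[0]
        return wrap


@njit(cache=True)
def _im2col_jit(xp, cols, k, s):
    # one streaming pass over output voxels; each writes k^3*C contiguous
    # destination elements from k^2 contiguous (l, c) source chunks
    n, _, _, _, c = xp.shape
    _, do, ho, wo, _, _ = cols.shape
    kc = k * c
    for b in range(n):
        for d in range(do):
            for h in range(ho):
                for w in range(wo):
                    for i in range(k):
                        for j in range(k):
                            ij = i * k + j
                            src = xp[b, d * s + i, h * s + j]
                            for l in range(k):
                                lc = l * c
                                for ch in range(c):
                                    cols[b, d, h, w, ij, lc + ch] = src[w * s + l, ch]


@njit(cache=True)
def _col2im_jit(dxp, dc, k, s):
    n, do, ho, wo = dc.shape[0], dc.shape[1], dc.shape[2], dc.shape[3]
    c = dxp.shape[4]
    for b in range(n):
        for d in range(do):
            for h in range(ho):
                for w in range(wo):
                    for i in range(k):
                        for j in range(k):
                            dst = dxp[b, d * s + i, h * s + j]
                            for l in range(k):
                                for ch in range(c):
                                    dst[w * s + l, ch] += dc[b, d, h, w, i, j, l, ch]


def im2col(xp: np.ndarray, k: int, s: int):
    """Unfold a padded channels-last volume into GEMM columns.

    Returns (cols, out_spatial): cols has one row per output voxel and
    k^3 * C columns ordered (i, j, l, c), matching W.reshape(k^3*C, O).
    """
    n, dp, hp, wp, c = xp.shape
    do, ho, wo = (dp - k) // s + 1, (hp - k) // s + 1, (wp - k) // s + 1
    cols = np.empty((n, do, ho, wo, k * k, k * c), dtype=xp.dtype)
    if HAVE_NUMBA:
        _im2col_jit(xp, cols, k, s)
    else:
        for i in range(k):
            for j in range(k):
                win = np.lib.stride_tricks.as_strided(
                    xp[:, i, j],
                    shape=(n, do, ho, wo, k * c),
                    strides=(xp.strides[0], s * xp.strides[1], s * xp.strides[2],
                             s * xp.strides[3], xp.itemsize),
                )
                cols[:, :, :, :, i * k + j, :] = win
    return cols.reshape(n * do * ho * wo, k**3 * c), (do, ho, wo)


def col2im_acc(dxp: np.ndarray, dcols: np.ndarray, out_spatial, k: int, s: int) -> None:
    """Scatter-add column gradients back onto the padded input gradient."""
    n = dxp.shape[0]
    do, ho, wo = out_spatial
    c = dxp.shape[4]
    dc = dcols.reshape(n, do, ho, wo, k, k, k, c)
    if HAVE_NUMBA:
        _col2im_jit(dxp, np.ascontiguousarray(dc), k, s)
    else:
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s, :] += \
                        dc[:, :, :, :, i, j, l, :]
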