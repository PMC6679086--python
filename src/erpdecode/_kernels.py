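"""Numba-JIT inner loops for the convolution layers.

These are drop-in replacements for the NumPy/BLAS formulations in
:mod:`erpdecode.nn`; the layer classes fall back to pure NumPy when numba
is unavailable.  All kernels are single-threaded and dtype-generic (lazy
specialization), so float32 training and float64 gradient checks both work.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False, fastmath=True)
def temporal_conv_fwd(xp, W, T):
    """xp (B, C, T+K-1) padded input, W (F, K) -> y (F, B, C, T)."""
    B, C, _ = xp.shape
    F, K = W.shape
    y = np.zeros((F, B, C, T), dtype=xp.dtype)
    for f in range(F):
        for b in range(B):
            for c in range(C):
                for k in range(K):
                    w = W[f, k]
                    for t in range(T):
                        y[f, b, c, t] += w * xp[b, c, t + k]
    return y


@njit(cache=False, fastmath=True)
def temporal_conv_dw(dy, xp):
    """dy (F, B, C, T), xp (B, C, T+K-1) -> dW (F, K)."""
    F, B, C, T = dy.shape
    K = xp.shape[2] - T + 1
    dW = np.zeros((F, K), dtype=dy.dtype)
    for f in range(F):
        for b in range(B):
            for c in range(C):
                for k in range(K):
                    s = dy.dtype.type(0.0)
                    for t in range(T):
                        s += dy[f, b, c, t] * xp[b, c, t + k]
                    dW[f, k] += s
    return dW


@njit(cache=False, fastmath=True)
def temporal_conv_dx(dy, W):
    """dy (F, B, C, T), W (F, K) -> dxp (B, C, T+K-1) (padded-domain grad)."""
    F, B, C, T = dy.shape
    K = W.shape[1]
    dxp = np.zeros((B, C, T + K - 1), dtype=dy.dtype)
    for f in range(F):
        for b in range(B):
            for c in range(C):
                for k in range(K):
                    w = W[f, k]
                    for t in range(T):
                        dxp[b, c, t + k] += w * dy[f, b, c, t]
    return dxp


@njit(cache=False, fastmath=True)
def spatial_conv_fwd(x, W):
    """x (F, B, C, T), W (F, D, C) -> y (B, F*D, T)."""
    F, B, C, T = x.shape
    D = W.shape[1]
    y = np.zeros((B, F * D, T), dtype=x.dtype)
    for b in range(B):
        for f in range(F):
            for d in range(D):
                m = f * D + d
                for c in range(C):
                    w = W[f, d, c]
                    for t in range(T):
                        y[b, m, t] += w * x[f, b, c, t]
    return y


@njit(cache=False, fastmath=True)
def spatial_conv_bwd(dy, x, W):
    """dy (B, F*D, T), x (F, B, C, T), W (F, D, C) -> (dW, dx)."""
    F, B, C, T = x.shape
    D = W.shape[1]
    dW = np.zeros_like(W)
    dx = np.zeros_like(x)
    for b in range(B):
        for f in range(F):
            for d in range(D):
                m = f * D + d
                for c in range(C):
                    w = W[f, d, c]
                    s = x.dtype.type(0.0)
                    for t in range(T):
                        s += dy[b, m, t] * x[f, b, c, t]
                        dx[f, b, c, t] += w * dy[b, m, t]
                    dW[f, d, c] += s
    return dW, dx
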