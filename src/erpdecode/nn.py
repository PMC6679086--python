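"""Minimal NumPy layer library with manual backpropagation.

Implements exactly the pieces the compact ERP classifier needs — temporal
convolution, depthwise spatial convolution, separable (depthwise + pointwise)
convolution, batch normalization, ELU, average pooling, dropout, and a dense
head — together with an Adam optimizer.  All computation is float32; forward
passes cache what backward needs, and ``backward`` can optionally propagate
the gradient all the way to the input (used for saliency maps).

Array conventions
-----------------
A batch of trials enters as ``(B, C, T)`` (trials, channels, samples).  The
temporal convolution expands it to ``(B, F, C, T)``; the depthwise spatial
convolution collapses the channel axis to ``(B, M, T)`` with ``M = F1 * D``
feature maps, which is the shape all later layers operate on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels

DTYPE = np.float32
USE_NUMBA = _kernels.HAVE_NUMBA  # module switch; NumPy path used when False


def _same_pad(kernel: int) -> tuple[int, int]:
    # TF "same" convention for stride 1: total pad = kernel - 1, extra on the right
    return (kernel - 1) // 2, kernel // 2


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class TemporalConv(Layer):
    """F filters of width K convolved along time, shared across channels.

    (B, C, T) -> (F, B, C, T) features-first, zero "same" padding, no bias.
    The filter axis leads inside block 1 so the convolution and batch-norm
    reduce/broadcast along contiguous rows; the depthwise spatial layer
    collapses the layout back to (B, M, T).
    """

    def __init__(self, n_filters: int, kernel: int, rng) -> None:
        super().__init__()
        self.K = kernel
        self.F = n_filters
        self.params["W"] = glorot_uniform(rng, (n_filters, kernel), kernel, n_filters)

    need_dx = True  # set False by Sequential.backward when the input grad is unused

    def forward(self, x, training, rng):
        B, C, T = x.shape
        self._bct = (B, C, T)
        pl, pr = _same_pad(self.K)
        xp = np.ascontiguousarray(np.pad(x, ((0, 0), (0, 0), (pl, pr))))
        if USE_NUMBA:
            self._xp, self._xcol = xp, None
            return _kernels.temporal_conv_fwd(xp, self.params["W"], T)
        win = sliding_window_view(xp, self.K, axis=-1)  # (B, C, T, K) view
        self._xp = None
        self._xcol = np.ascontiguousarray(win).reshape(B * C * T, self.K)
        y = self.params["W"] @ self._xcol.T  # (F, N)
        return y.reshape(self.F, B, C, T)

    def backward(self, dy):
        # dy: (F, B, C, T)
        B, C, T = self._bct
        pl, pr = _same_pad(self.K)
        dy = np.ascontiguousarray(dy)
        if USE_NUMBA:
            self.grads["W"] = _kernels.temporal_conv_dw(dy, self._xp)
            if not self.need_dx:
                return None
            dxp = _kernels.temporal_conv_dx(dy, self.params["W"])
            return np.ascontiguousarray(dxp[:, :, pl : pl + T])
        dy2 = dy.reshape(self.F, -1)
        self.grads["W"] = dy2 @ self._xcol  # (F, K)
        if not self.need_dx:
            return None
        dxcol = self.params["W"].T @ dy2  # (K, N)
        dxp = np.zeros((B, C, T + self.K - 1), dtype=dy.dtype)
        for k in range(self.K):  # col2im scatter-add
            dxp[:, :, k : k + T] += dxcol[k].reshape(B, C, T)
        return np.ascontiguousarray(dxp[:, :, pl : pl + T])


class DepthwiseSpatialConv(Layer):
    """D spatial filters per temporal map, spanning all C channels.

    (F, B, C, T) features-first -> (B, F*D, T), "valid" over the channel
    axis, no bias.
    """

    def __init__(self, n_temporal: int, depth_mult: int, n_channels: int, rng) -> None:
        super().__init__()
        self.F, self.D, self.C = n_temporal, depth_mult, n_channels
        self.params["W"] = glorot_uniform(
            rng, (n_temporal, depth_mult, n_channels), n_channels, depth_mult
        )

    def forward(self, x, training, rng):
        self._x = np.ascontiguousarray(x)  # (F, B, C, T)
        if USE_NUMBA:
            return _kernels.spatial_conv_fwd(self._x, self.params["W"])
        y = np.einsum("fbct,fdc->bfdt", self._x, self.params["W"], optimize=True)
        B = x.shape[1]
        return np.ascontiguousarray(y.reshape(B, self.F * self.D, -1))

    def backward(self, dy):
        B, M, T = dy.shape
        if USE_NUMBA:
            dW, dx = _kernels.spatial_conv_bwd(
                np.ascontiguousarray(dy), self._x, self.params["W"]
            )
            self.grads["W"] = dW
            return dx
        dy4 = dy.reshape(B, self.F, self.D, T)
        self.grads["W"] = np.einsum("bfdt,fbct->fdc", dy4, self._x, optimize=True)
        return np.ascontiguousarray(
            np.einsum("bfdt,fdc->fbct", dy4, self.params["W"], optimize=True)
        )


class SeparableConv(Layer):
    """Depthwise temporal convolution followed by pointwise (1x1) mixing.

    (B, M, T) -> (B, N, T); per-map kernels of width K ("same"), no biases.
    """

    def __init__(self, n_in: int, n_out: int, kernel: int, rng) -> None:
        super().__init__()
        self.K, self.M, self.N = kernel, n_in, n_out
        self.params["Wd"] = glorot_uniform(rng, (n_in, kernel), kernel, 1)
        self.params["Wp"] = glorot_uniform(rng, (n_out, n_in), n_in, n_out)

    def forward(self, x, training, rng):
        self._x = x
        pl, pr = _same_pad(self.K)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._win = sliding_window_view(xp, self.K, axis=-1)  # (B, M, T, K)
        self._depth = np.einsum("bmtk,mk->bmt", self._win, self.params["Wd"], optimize=True)
        return np.einsum("bmt,nm->bnt", self._depth, self.params["Wp"], optimize=True)

    def backward(self, dy):
        self.grads["Wp"] = np.einsum("bnt,bmt->nm", dy, self._depth, optimize=True)
        dd = np.einsum("bnt,nm->bmt", dy, self.params["Wp"], optimize=True)  # (B, M, T)
        self.grads["Wd"] = np.einsum("bmt,bmtk->mk", dd, self._win, optimize=True)
        K = self.K
        pl, _ = _same_pad(K)
        ddp = np.pad(dd, ((0, 0), (0, 0), (K - 1, K - 1)))
        dwin = sliding_window_view(ddp, K, axis=-1)
        dxp = np.einsum("bmsk,mk->bms", dwin, self.params["Wd"][:, ::-1], optimize=True)
        T = dy.shape[-1]
        return np.ascontiguousarray(dxp[..., pl : pl + T])


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    Training uses batch statistics (biased variance) and updates running
    buffers with momentum 0.1; inference uses the running buffers.  The
    feature axis is 1 by default; ``feature_axis=-1`` supports the
    channels-last layout of block 1.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 feature_axis: int = 1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.axis = feature_axis
        self.params["gamma"] = np.ones(n_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_features, dtype=DTYPE)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)

    def _axes_shape(self, ndim):
        ax = self.axis % ndim
        axes = tuple(i for i in range(ndim) if i != ax)
        sh = [1] * ndim
        sh[ax] = -1
        return axes, tuple(sh)

    def forward(self, x, training, rng):
        axes, sh = self._axes_shape(x.ndim)
        self._training = training
        if training:
            x2 = x.reshape(self.params["gamma"].size, -1) if self.axis == 0 else None
            if x2 is not None:
                n = x2.shape[1]
                mean = x2.mean(axis=1)
                var = np.maximum(np.einsum("fn,fn->f", x2, x2) / n - mean * mean, 0.0)
            else:
                mean = x.mean(axis=axes)
                var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var.astype(np.float64) + self.eps)).astype(DTYPE)
        self._mean, self._inv = np.asarray(mean, dtype=DTYPE), inv
        self._x = x
        g = (self.params["gamma"] * inv).reshape(sh)
        b = (self.params["beta"] - self.params["gamma"] * inv * self._mean).reshape(sh)
        return x * g + b

    def backward(self, dy):
        axes, sh = self._axes_shape(dy.ndim)
        n = dy.size // self.params["gamma"].size
        gamma, inv, mean = self.params["gamma"], self._inv, self._mean
        if self.axis == 0:
            F = gamma.size
            sum_dy = dy.reshape(F, -1).sum(axis=1)
            sum_dyx = np.einsum("fn,fn->f", dy.reshape(F, -1), self._x.reshape(F, -1))
        else:
            sum_dy = dy.sum(axis=axes)
            sum_dyx = (dy * self._x).sum(axis=axes)
        # sum of dy * xhat, without materializing xhat
        sum_dyxhat = (sum_dyx - mean * sum_dy) * inv
        self.grads["gamma"] = sum_dyxhat.astype(DTYPE)
        self.grads["beta"] = sum_dy.astype(DTYPE)
        if not self._training:
            return dy * (gamma * inv).reshape(sh)
        # dx = a*dy + b*x + c with per-feature scalars (standard BN backward
        # algebra, rearranged into two fused elementwise passes)
        a = gamma * inv
        b = -(gamma * inv / n) * sum_dyxhat * inv
        c = -(gamma * inv / n) * sum_dy - b * mean
        return dy * a.reshape(sh) + self._x * b.reshape(sh) + c.reshape(sh)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training, rng):
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._neg, self._y = neg, y
        return y.astype(DTYPE, copy=False)

    def backward(self, dy):
        return np.where(self._neg, dy * (self._y + self.alpha), dy)


class AvgPool(Layer):
    """Average pooling over the last axis with stride = width (truncating)."""

    def __init__(self, width: int) -> None:
        super().__init__()
        self.p = width

    def forward(self, x, training, rng):
        self._T = x.shape[-1]
        n = self._T // self.p
        self._n = n
        xt = x[..., : n * self.p]
        return xt.reshape(*x.shape[:-1], n, self.p).mean(axis=-1)

    def backward(self, dy):
        dx = np.zeros(dy.shape[:-1] + (self._T,), dtype=DTYPE)
        dx[..., : self._n * self.p] = np.repeat(dy / self.p, self.p, axis=-1)
        return dx


class Dropout(Layer):
    """Inverted dropout: scales kept activations by 1/(1-rate) in training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias (the classification head)."""

    def __init__(self, n_in: int, n_out: int, rng) -> None:
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential:
    """Ordered (name, layer) stack with end-to-end forward/backward."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        self.layers = layers

    def forward(self, x, training: bool = False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        for _, layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy, to_input: bool = False):
        dy = np.asarray(dy, dtype=DTYPE)
        first = self.layers[0][1]
        if isinstance(first, TemporalConv):
            first.need_dx = to_input
        try:
            for _, layer in reversed(self.layers):
                dy = layer.backward(dy)
        finally:
            if isinstance(first, TemporalConv):
                first.need_dx = True
        return dy

    def parameter_items(self):
        for name, layer in self.layers:
            for pname in layer.params:
                yield f"{name}.{pname}", layer, pname

    def n_params(self) -> int:
        return sum(layer.n_params() for _, layer in self.layers)

    def get_state(self) -> dict:
        state = {}
        for name, layer in self.layers:
            for pname, val in layer.params.items():
                state[f"{name}.{pname}"] = val.copy()
            if isinstance(layer, BatchNorm):
                state[f"{name}._running_mean"] = layer.running_mean.copy()
                state[f"{name}._running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for name, layer in self.layers:
            for pname in layer.params:
                layer.params[pname] = state[f"{name}.{pname}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{name}._running_mean"].copy()
                layer.running_var = state[f"{name}._running_var"].copy()


class Adam:
    """Adam optimizer with the conventional defaults."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[p]) for k, layer, p in model.parameter_items()}
        self.v = {k: np.zeros_like(layer.params[p]) for k, layer, p in model.parameter_items()}

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for key, layer, pname in self.model.parameter_items():
            g = layer.grads[pname]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            layer.params[pname] -= (
                lr_t * self.m[key] / (np.sqrt(self.v[key]) + self.eps)
            ).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits, labels, sample_weights=None):
    """Mean (optionally sample-weighted) cross-entropy and its logit gradient."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ll = -np.log(p[np.arange(B), labels] + eps)
    if sample_weights is None:
        loss = ll.mean()
        dp = p
        dp[np.arange(B), labels] -= 1.0
        dlogits = dp / B
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
        loss = (w * ll).mean()
        dp = p * w[:, None]
        dp[np.arange(B), labels] -= w
        dlogits = dp / B
    return loss, dlogits.astype(DTYPE)
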