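"""Small NumPy layer engine with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward`` while
accumulating parameter gradients in :class:`Parameter` objects.  The
engine is deliberately minimal: it supports exactly the operations the
GDNet architecture needs (temporal convolution shared across EEG
channels, per-channel grouped convolution, depth-wise spatial and
point-wise convolutions, batch normalisation, the usual activations,
dropout and a dense head) plus the sigmoid-gated attention layers
defined in :mod:`gdnet.attention`.

Conventions
-----------
* Feature cubes are ``(batch, C, M, L)`` arrays: EEG channel ``C``,
  feature map ``M``, feature length ``L``.
* Raw segments enter as ``(batch, C, L)``.
* Parameters are float32 by default; ``Network.astype`` converts a whole
  network to float64, which the numerical gradient checks in the test
  suite rely on.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

DEFAULT_DTYPE = np.float32


# ---------------------------------------------------------------------------
# parameters and helpers
# ---------------------------------------------------------------------------

class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay=True`` marks the parameter as part of the L2 penalty
    (convolution/dense/attention weight matrices; biases and batch-norm
    scale/shift are excluded).
    """

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool = False):
        self.name = name
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """SAME-padding arithmetic: output length ``ceil(L/s)`` and the left/right pad."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


def _windows(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Sliding windows along the last axis of a C-contiguous array (a view)."""
    length = x.shape[-1]
    n_out = (length - kernel) // stride + 1
    shape = x.shape[:-1] + (n_out, kernel)
    strides = x.strides[:-1] + (x.strides[-1] * stride, x.strides[-1])
    return as_strided(x, shape=shape, strides=strides)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layer base class
# ---------------------------------------------------------------------------

class Layer:
    """Base class: sub-classes implement ``forward`` and ``backward``."""

    def __init__(self) -> None:
        self._params: list[Parameter] = []

    def _add_param(self, name: str, value: np.ndarray, decay: bool = False) -> Parameter:
        p = Parameter(name, value, decay=decay)
        self._params.append(p)
        return p

    def parameters(self) -> list[Parameter]:
        return list(self._params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def astype(self, dtype) -> None:
        for p in self._params:
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

class TemporalConv(Layer):
    """Regular temporal convolution: one 1x`kernel` filter per feature map.

    The same kernel slides over every EEG channel (SAME padding, stride 1),
    turning a ``(B, C, L)`` segment into a ``(B, C, M, L)`` feature cube.
    No bias: the layer is immediately followed by batch normalisation.
    """

    def __init__(self, n_maps: int, kernel: int = 17, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_maps = n_maps
        self.kernel = kernel
        self.weight = self._add_param(
            "temporal_conv.weight", np.zeros((n_maps, kernel), dtype=dtype), decay=True
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        batch, n_ch, length = x.shape
        _, left, right = same_pad(length, self.kernel, 1)
        xp = np.pad(x, [(0, 0), (0, 0), (left, right)])
        cols = _windows(xp, self.kernel, 1)                    # (B, C, L, k) view
        self._cols = cols
        self._shape = (batch, n_ch, length)
        out = cols.reshape(-1, self.kernel) @ self.weight.value.T
        out = out.reshape(batch, n_ch, length, self.n_maps)
        return np.ascontiguousarray(out.transpose(0, 1, 3, 2))  # (B, C, M, L)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        batch, n_ch, length = self._shape
        g = np.ascontiguousarray(grad_out.transpose(0, 1, 3, 2)).reshape(-1, self.n_maps)
        cols = self._cols.reshape(-1, self.kernel)
        self.weight.grad += g.T @ cols
        dcols = (g @ self.weight.value).reshape(batch, n_ch, length, self.kernel)
        _, left, right = same_pad(length, self.kernel, 1)
        dxp = np.zeros((batch, n_ch, length + left + right), dtype=g.dtype)
        for t in range(self.kernel):
            dxp[:, :, t:t + length] += dcols[:, :, :, t]
        return dxp[:, :, left:left + length]


class GroupDepthwiseConv(Layer):
    """Group depth-wise convolution: an independent 1D kernel per EEG channel.

    Output row for map ``i``, channel ``c``:

        Y[i, c] = b[c, i] + sum_j  K[c, i, j] * Y_in[j, c]        (stride s)

    i.e. every EEG channel carries its own bank of temporal kernels, so
    different channels learn different frequency content.  Weight shape is
    ``(C, M_out, M_in, kernel)``; SAME padding with stride ``s`` gives
    output length ``ceil(L / s)``.
    """

    def __init__(self, n_channels: int, in_maps: int, out_maps: int,
                 kernel: int = 17, stride: int = 2, bias: bool = True,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_channels = n_channels
        self.in_maps = in_maps
        self.out_maps = out_maps
        self.kernel = kernel
        self.stride = stride
        self.weight = self._add_param(
            "group_conv.weight",
            np.zeros((n_channels, out_maps, in_maps, kernel), dtype=dtype),
            decay=True,
        )
        self.bias = None
        if bias:
            self.bias = self._add_param(
                "group_conv.bias", np.zeros((n_channels, out_maps), dtype=dtype)
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        batch, n_ch, in_maps, length = x.shape
        if n_ch != self.n_channels or in_maps != self.in_maps:
            raise ValueError(
                f"group conv expects cube (*, {self.n_channels}, {self.in_maps}, L), "
                f"got {x.shape}"
            )
        out_len, left, right = same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, [(0, 0), (0, 0), (0, 0), (left, right)])
        cols = _windows(xp, self.kernel, self.stride)          # (B, C, Mi, Lo, k)
        # (C, B*Lo, Mi*k) layout so the whole conv is one batched matmul over C
        cols_m = np.ascontiguousarray(cols.transpose(1, 0, 3, 2, 4)).reshape(
            n_ch, batch * out_len, in_maps * self.kernel
        )
        w_m = np.ascontiguousarray(self.weight.value.transpose(0, 2, 3, 1)).reshape(
            n_ch, in_maps * self.kernel, self.out_maps
        )
        out = cols_m @ w_m                                     # (C, B*Lo, Mo)
        if self.bias is not None:
            out += self.bias.value[:, None, :]
        self._cache = (cols_m, batch, length, out_len, left, right)
        out = out.reshape(n_ch, batch, out_len, self.out_maps)
        return np.ascontiguousarray(out.transpose(1, 0, 3, 2))  # (B, C, Mo, Lo)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols_m, batch, length, out_len, left, right = self._cache
        n_ch, in_maps, k, s = self.n_channels, self.in_maps, self.kernel, self.stride
        g = np.ascontiguousarray(grad_out.transpose(1, 0, 3, 2)).reshape(
            n_ch, batch * out_len, self.out_maps
        )
        dw_m = cols_m.transpose(0, 2, 1) @ g                   # (C, Mi*k, Mo)
        self.weight.grad += np.ascontiguousarray(
            dw_m.reshape(n_ch, in_maps, k, self.out_maps).transpose(0, 3, 1, 2)
        )
        if self.bias is not None:
            self.bias.grad += g.sum(axis=1)
        w_m = np.ascontiguousarray(self.weight.value.transpose(0, 2, 3, 1)).reshape(
            n_ch, in_maps * k, self.out_maps
        )
        dcols = (g @ w_m.transpose(0, 2, 1)).reshape(n_ch, batch, out_len, in_maps, k)
        dcols = np.ascontiguousarray(dcols.transpose(1, 0, 3, 2, 4))  # (B,C,Mi,Lo,k)
        dxp = np.zeros((batch, n_ch, in_maps, length + left + right), dtype=g.dtype)
        for t in range(k):
            dxp[:, :, :, t:t + (out_len - 1) * s + 1:s] += dcols[:, :, :, :, t]
        return dxp[:, :, :, left:left + length]


class RegularConv(Layer):
    """Standard 2D convolution with a 1x`kernel` receptive field, shared
    across EEG channels — the ablation replacement for the group block.

    Weight shape ``(M_out, M_in, kernel)``; bias per output map.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int = 17,
                 stride: int = 2, bias: bool = True, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_maps = in_maps
        self.out_maps = out_maps
        self.kernel = kernel
        self.stride = stride
        self.weight = self._add_param(
            "regular_conv.weight",
            np.zeros((out_maps, in_maps, kernel), dtype=dtype), decay=True,
        )
        self.bias = None
        if bias:
            self.bias = self._add_param(
                "regular_conv.bias", np.zeros(out_maps, dtype=dtype)
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        batch, n_ch, in_maps, length = x.shape
        out_len, left, right = same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, [(0, 0), (0, 0), (0, 0), (left, right)])
        cols = _windows(xp, self.kernel, self.stride)          # (B, C, Mi, Lo, k)
        cols_m = np.ascontiguousarray(cols.transpose(0, 1, 3, 2, 4)).reshape(
            -1, in_maps * self.kernel
        )
        w_m = self.weight.value.reshape(self.out_maps, -1)
        out = cols_m @ w_m.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols_m, batch, n_ch, length, out_len, left, right)
        out = out.reshape(batch, n_ch, out_len, self.out_maps)
        return np.ascontiguousarray(out.transpose(0, 1, 3, 2))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols_m, batch, n_ch, length, out_len, left, right = self._cache
        k, s = self.kernel, self.stride
        g = np.ascontiguousarray(grad_out.transpose(0, 1, 3, 2)).reshape(-1, self.out_maps)
        self.weight.grad += (g.T @ cols_m).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = (g @ self.weight.value.reshape(self.out_maps, -1)).reshape(
            batch, n_ch, out_len, self.in_maps, k
        )
        dcols = np.ascontiguousarray(dcols.transpose(0, 1, 3, 2, 4))
        dxp = np.zeros((batch, n_ch, self.in_maps, length + left + right), dtype=g.dtype)
        for t in range(k):
            dxp[:, :, :, t:t + (out_len - 1) * s + 1:s] += dcols[:, :, :, :, t]
        return dxp[:, :, :, left:left + length]


class DepthwiseSpatialConv(Layer):
    """Depth-wise spatial convolution: per feature map, a Cx1 kernel collapses
    the EEG-channel dimension (VALID padding), ``(B,C,M,L) -> (B,M,L)``."""

    def __init__(self, n_channels: int, n_maps: int, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_channels = n_channels
        self.n_maps = n_maps
        self.weight = self._add_param(
            "spatial_conv.weight", np.zeros((n_maps, n_channels), dtype=dtype), decay=True
        )
        self.bias = self._add_param("spatial_conv.bias", np.zeros(n_maps, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        if x.shape[1] != self.n_channels:
            raise ValueError(
                f"spatial kernel spans {self.n_channels} channels, input has {x.shape[1]}"
            )
        self._x = x
        out = np.einsum("bcml,mc->bml", x, self.weight.value, optimize=True)
        return out + self.bias.value[None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("bml,bcml->mc", grad_out, self._x, optimize=True)
        self.bias.grad += grad_out.sum(axis=(0, 2))
        return np.einsum("bml,mc->bcml", grad_out, self.weight.value, optimize=True)


class PointwiseConv(Layer):
    """1x1 convolution mixing feature maps: ``(B, M_in, L) -> (B, M_out, L)``.

    No bias (batch norm follows in the network).
    """

    def __init__(self, in_maps: int, out_maps: int, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_maps = in_maps
        self.out_maps = out_maps
        self.weight = self._add_param(
            "pointwise_conv.weight", np.zeros((out_maps, in_maps), dtype=dtype), decay=True
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        self._x = x
        return np.einsum("bml,nm->bnl", x, self.weight.value, optimize=True)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("bnl,bml->nm", grad_out, self._x, optimize=True)
        return np.einsum("bnl,nm->bml", grad_out, self.weight.value, optimize=True)


# ---------------------------------------------------------------------------
# normalisation, activations, dropout
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Batch normalisation over the feature-map axis.

    Accepts ``(B, C, M, L)`` cubes (normalising over B, C, L) or
    ``(B, M, L)`` arrays (normalising over B, L).  Library-default
    momentum 0.1 and epsilon 1e-5.
    """

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_maps = n_maps
        self.momentum = momentum
        self.eps = eps
        self.gamma = self._add_param("batchnorm.scale", np.ones(n_maps, dtype=dtype))
        self.beta = self._add_param("batchnorm.shift", np.zeros(n_maps, dtype=dtype))
        self.running_mean = np.zeros(n_maps, dtype=dtype)
        self.running_var = np.ones(n_maps, dtype=dtype)

    def _axes_and_shape(self, x: np.ndarray):
        if x.ndim == 4:
            return (0, 1, 3), (1, 1, self.n_maps, 1)
        if x.ndim == 3:
            return (0, 2), (1, self.n_maps, 1)
        raise ValueError(f"batch norm expects 3D or 4D input, got shape {x.shape}")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.gamma.value.dtype, copy=False)
        axes, bshape = self._axes_and_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * inv_std.reshape(bshape)
        self._cache = (xhat, inv_std, axes, bshape, x.size // self.n_maps)
        return self.gamma.value.reshape(bshape) * xhat + self.beta.value.reshape(bshape)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, bshape, n = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.value.reshape(bshape)
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        return inv_std.reshape(bshape) * (g - gsum / n - xhat * gxsum / n)

    def astype(self, dtype) -> None:
        super().astype(dtype)
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.slope = negative_slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.slope
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dx = grad_out.copy()
        dx[self._neg] *= self.slope
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        neg = x < 0
        out = x.copy()
        out[neg] = self.alpha * np.expm1(x[neg])
        self._neg, self._out_neg = neg, out[neg]
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dx = grad_out.copy()
        dx[self._neg] *= self._out_neg + self.alpha
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training. The mask RNG is set by
    ``Network.set_rng`` so training runs are reproducible from one seed."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with identity activation and no bias term:
    ``Z_i = sum_j w_ij z_j``."""

    def __init__(self, n_in: int, n_out: int, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_in = n_in
        self.n_out = n_out
        self.weight = self._add_param(
            "dense.weight", np.zeros((n_out, n_in), dtype=dtype), decay=True
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        if x.shape[1] != self.n_in:
            raise ValueError(f"dense layer expects {self.n_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.weight.value.T

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        return grad_out @ self.weight.value


# ---------------------------------------------------------------------------
# network container, loss, optimizer
# ---------------------------------------------------------------------------

class Network:
    """A plain sequential container of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for i, layer in enumerate(self.layers):
            for p in layer.parameters():
                out[f"layer{i:02d}.{p.name}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
            for sub in getattr(layer, "sublayers", lambda: [])():
                if isinstance(sub, Dropout):
                    sub.rng = rng

    def astype(self, dtype) -> "Network":
        for layer in self.layers:
            layer.astype(dtype)
        return self

    # -- weight (de)serialisation ------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value.copy() for name, p in self.parameters().items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"layer{i:02d}.batchnorm.running_mean"] = layer.running_mean.copy()
                state[f"layer{i:02d}.batchnorm.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for name, p in params.items():
            p.value = np.array(state[name], dtype=p.value.dtype)
            p.grad = np.zeros_like(p.value)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(
                    state[f"layer{i:02d}.batchnorm.running_mean"],
                    dtype=layer.running_mean.dtype)
                layer.running_var = np.array(
                    state[f"layer{i:02d}.batchnorm.running_var"],
                    dtype=layer.running_var.dtype)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.  Softmax probabilities are clamped
    at ``eps`` before the log so a confidently wrong prediction yields a
    large finite loss rather than an infinity.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    picked = np.clip(probs[np.arange(n), labels], eps, None)
    loss = float(-np.log(picked).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def l2_penalty(params: Iterable[Parameter], lam: float) -> float:
    """``lam * sum(w^2)`` over decaying parameters (exact, no 1/2 factor)."""
    total = 0.0
    for p in params:
        if p.decay:
            total += float(np.sum(np.square(p.value.astype(np.float64))))
    return lam * total


def add_l2_gradients(params: Iterable[Parameter], lam: float) -> None:
    """Accumulate d/dw of ``lam * |w|^2`` (= ``2 lam w``) into the gradients."""
    for p in params:
        if p.decay:
            p.grad += 2.0 * lam * p.value


class Adam:
    """Adam optimizer with the standard defaults."""

    def __init__(self, params: dict[str, Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def output_length_after_blocks(n_samples: int, n_blocks: int, stride: int = 2) -> int:
    """Feature length after ``n_blocks`` SAME-padded stride-``stride`` blocks
    (the ceil-division chain, e.g. 250 -> 125 -> 63 -> 32 -> 16)."""
    length = n_samples
    for _ in range(n_blocks):
        length = -(-length // stride)
    return length
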