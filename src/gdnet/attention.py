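"""Two-stage EEG attention: channel-wise and specialized network-wise gates.

The module refines a feature cube ``F`` of shape ``(C, M, L)`` — EEG
channel x feature map x feature length — in two sequential stages:

1. **EEG channel-wise attention.**  Each feature map is average- and
   max-pooled along its feature-length axis, giving two ``C x M``
   descriptors.  Per feature map, a learned 1x1 filter (an affine
   combination of the pooled pair, shared across EEG channels within
   that map) produces a pre-activation, and a sigmoid yields the gate
   matrix ``M_EC in (0,1)^{C x M}``.  The refined cube is
   ``F'[c,m,:] = M_EC[c,m] * F[c,m,:]`` — the gate identifies the EEG
   channels (brain regions) essential to each map.

2. **Specialized network-wise attention.**  ``F'`` is globally average-
   and max-pooled over channels and length, giving two length-``M``
   descriptors.  A shared one-hidden-layer MLP (``W0: M -> M/r``, ReLU,
   ``W1: M/r -> M``, no biases) maps each; the outputs are summed
   element-wise and a sigmoid yields ``M_SN in (0,1)^M``.  The final
   cube is ``F''[c,m,:] = M_SN[m] * F'[c,m,:]`` — each feature map is
   read as a specialized brain network and weighted by importance.

Both gates lie strictly inside (0, 1), so the module preserves shape and
is elementwise contractive: ``|F''| <= |F|``.

The functional API (:func:`channel_attention` etc.) operates on single
unbatched cubes and mirrors the algebra one-to-one; the ``*Layer``
classes are the batched, differentiable versions used inside the
network, plus a CBAM block used as an ablation stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import DEFAULT_DTYPE, Layer, Parameter, sigmoid


# ---------------------------------------------------------------------------
# functional API on unbatched (C, M, L) cubes
# ---------------------------------------------------------------------------

@dataclass
class ChannelAttentionParams:
    """Per-map 1x1 mixing of the (avg, max) pooled descriptor pair.

    ``weights`` has shape (M, 2): column 0 multiplies the average-pooled
    descriptor, column 1 the max-pooled one; ``bias`` has shape (M,).
    """

    weights: np.ndarray
    bias: np.ndarray

    @classmethod
    def zeros(cls, n_maps: int) -> "ChannelAttentionParams":
        return cls(np.zeros((n_maps, 2)), np.zeros(n_maps))


@dataclass
class NetworkAttentionParams:
    """Shared-MLP weights: ``w0`` (M, M/r) then ReLU then ``w1`` (M/r, M)."""

    w0: np.ndarray
    w1: np.ndarray

    @classmethod
    def zeros(cls, n_maps: int, reduction: int = 8) -> "NetworkAttentionParams":
        hidden = max(1, n_maps // reduction)
        return cls(np.zeros((n_maps, hidden)), np.zeros((hidden, n_maps)))


def channel_attention(cube: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """EEG channel-wise attention map ``M_EC`` in ``(0,1)^{C x M}``."""
    if cube.ndim != 3:
        raise ValueError(f"expected a (C, M, L) cube, got shape {cube.shape}")
    if cube.shape[2] == 0:
        raise ValueError("feature length must be positive")
    avg = cube.mean(axis=2)                      # (C, M)
    mx = cube.max(axis=2)
    pre = avg * params.weights[:, 0] + mx * params.weights[:, 1] + params.bias
    return sigmoid(pre)


def apply_channel_attention(cube: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """``F'[c, m, :] = M_EC[c, m] * F[c, m, :]``."""
    if gate.shape != cube.shape[:2]:
        raise ValueError(f"gate shape {gate.shape} != cube (C, M) {cube.shape[:2]}")
    return cube * gate[:, :, None]


def network_attention(cube: np.ndarray, params: NetworkAttentionParams) -> np.ndarray:
    """Specialized network-wise attention vector ``M_SN`` in ``(0,1)^M``."""
    if cube.ndim != 3:
        raise ValueError(f"expected a (C, M, L) cube, got shape {cube.shape}")
    if cube.shape[1] != params.w0.shape[0]:
        raise ValueError("map count does not match W0")
    avg = cube.mean(axis=(0, 2))                 # (M,)
    mx = cube.max(axis=(0, 2))
    mlp = lambda d: np.maximum(d @ params.w0, 0.0) @ params.w1
    return sigmoid(mlp(avg) + mlp(mx))


def apply_network_attention(cube: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """``F''[c, m, :] = M_SN[m] * F'[c, m, :]``."""
    if gate.shape != (cube.shape[1],):
        raise ValueError(f"gate length {gate.shape} != map count {cube.shape[1]}")
    return cube * gate[None, :, None]


def eeg_attention(cube: np.ndarray, ch_params: ChannelAttentionParams,
                  net_params: NetworkAttentionParams) -> np.ndarray:
    """Full two-stage refinement ``F'' = M_SN (.) (M_EC (.) F)``."""
    refined = apply_channel_attention(cube, channel_attention(cube, ch_params))
    return apply_network_attention(refined, network_attention(refined, net_params))


# ---------------------------------------------------------------------------
# batched differentiable layers
# ---------------------------------------------------------------------------

class ChannelAttentionLayer(Layer):
    """Batched channel-wise gate applied in place: (B,C,M,L) -> (B,C,M,L)."""

    def __init__(self, n_maps: int, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_maps = n_maps
        self.weight = self._add_param(
            "channel_attn.weight", np.zeros((n_maps, 2), dtype=dtype), decay=True
        )
        self.bias = self._add_param("channel_attn.bias", np.zeros(n_maps, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.weight.value.dtype, copy=False)
        length = x.shape[3]
        avg = x.mean(axis=3)                         # (B, C, M)
        idx = x.argmax(axis=3)
        mx = np.take_along_axis(x, idx[..., None], axis=3)[..., 0]
        pre = avg * self.weight.value[:, 0] + mx * self.weight.value[:, 1] + self.bias.value
        gate = sigmoid(pre)
        self._cache = (x, avg, mx, idx, gate, length)
        return x * gate[..., None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, avg, mx, idx, gate, length = self._cache
        dx = grad_out * gate[..., None]
        dgate = (grad_out * x).sum(axis=3)
        dpre = dgate * gate * (1.0 - gate)
        self.weight.grad[:, 0] += (dpre * avg).sum(axis=(0, 1))
        self.weight.grad[:, 1] += (dpre * mx).sum(axis=(0, 1))
        self.bias.grad += dpre.sum(axis=(0, 1))
        davg = dpre * self.weight.value[:, 0]
        dx += davg[..., None] / length
        dmx = dpre * self.weight.value[:, 1]
        scatter = np.zeros_like(x)
        np.put_along_axis(scatter, idx[..., None], dmx[..., None], axis=3)
        return dx + scatter


class NetworkAttentionLayer(Layer):
    """Batched network-wise gate: shared bias-free MLP over global avg/max
    descriptors, sigmoid of the summed outputs, broadcast over (C, L)."""

    def __init__(self, n_maps: int, reduction: int = 8, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_maps = n_maps
        self.hidden = max(1, n_maps // reduction)
        self.w0 = self._add_param(
            "network_attn.w0", np.zeros((n_maps, self.hidden), dtype=dtype), decay=True
        )
        self.w1 = self._add_param(
            "network_attn.w1", np.zeros((self.hidden, n_maps), dtype=dtype), decay=True
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x.astype(self.w0.value.dtype, copy=False)
        batch, n_ch, n_maps, length = x.shape
        flat = np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(batch, n_maps, -1)
        avg = flat.mean(axis=2)                      # (B, M)
        idx = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]
        h_a = np.maximum(avg @ self.w0.value, 0.0)
        h_m = np.maximum(mx @ self.w0.value, 0.0)
        gate = sigmoid(h_a @ self.w1.value + h_m @ self.w1.value)
        self._cache = (x, avg, mx, idx, h_a, h_m, gate, n_ch * length)
        return x * gate[:, None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, avg, mx, idx, h_a, h_m, gate, pooled_n = self._cache
        batch, n_ch, n_maps, length = x.shape
        dx = grad_out * gate[:, None, :, None]
        dgate = (grad_out * x).sum(axis=(1, 3))      # (B, M)
        dpre = dgate * gate * (1.0 - gate)
        dh_a = (dpre @ self.w1.value.T) * (h_a > 0)
        dh_m = (dpre @ self.w1.value.T) * (h_m > 0)
        self.w1.grad += h_a.T @ dpre + h_m.T @ dpre
        self.w0.grad += avg.T @ dh_a + mx.T @ dh_m
        davg = dh_a @ self.w0.value.T                # (B, M)
        dmx = dh_m @ self.w0.value.T
        dx += davg[:, None, :, None] / pooled_n
        dflat = np.zeros((batch, n_maps, n_ch * length), dtype=x.dtype)
        np.put_along_axis(dflat, idx[..., None], dmx[..., None], axis=2)
        dx += dflat.reshape(batch, n_maps, n_ch, length).transpose(0, 2, 1, 3)
        return dx


class EEGAttentionLayer(Layer):
    """Channel-wise then network-wise gating, shape preserving."""

    def __init__(self, n_maps: int, reduction: int = 8,
                 channel_stage: bool = True, network_stage: bool = True,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.channel = ChannelAttentionLayer(n_maps, dtype=dtype) if channel_stage else None
        self.network = (NetworkAttentionLayer(n_maps, reduction, dtype=dtype)
                        if network_stage else None)

    def sublayers(self) -> list[Layer]:
        return [s for s in (self.channel, self.network) if s is not None]

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for s in self.sublayers():
            out.extend(s.parameters())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for s in self.sublayers():
            x = s.forward(x, training=training)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for s in reversed(self.sublayers()):
            grad_out = s.backward(grad_out)
        return grad_out

    def astype(self, dtype) -> None:
        for s in self.sublayers():
            s.astype(dtype)


class CBAMLayer(Layer):
    """Convolutional block attention module, the published channel-then-
    spatial attention block used as an ablation substitute.

    Channel stage: global avg/max descriptors per feature map through a
    shared reduction-``r`` MLP, summed, sigmoid -> per-map gate.
    Spatial stage: avg/max pooling over the map axis gives a 2-layer
    ``(C, L)`` descriptor; a kernel-``k`` convolution along the EEG-channel
    axis (SAME padding) and a sigmoid give a per-(channel, time) gate
    shared across maps.
    """

    def __init__(self, n_maps: int, reduction: int = 8, spatial_kernel: int = 7,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.n_maps = n_maps
        self.k = spatial_kernel
        self.channel = NetworkAttentionLayer(n_maps, reduction, dtype=dtype)
        self.sw = self._add_param(
            "cbam.spatial.weight", np.zeros((2, spatial_kernel), dtype=dtype), decay=True
        )
        self.sb = self._add_param("cbam.spatial.bias", np.zeros(1, dtype=dtype))

    def sublayers(self) -> list[Layer]:
        return [self.channel]

    def parameters(self) -> list[Parameter]:
        return self.channel.parameters() + list(self._params)

    def astype(self, dtype) -> None:
        super().astype(dtype)
        self.channel.astype(dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x1 = self.channel.forward(x, training=training)      # (B, C, M, L)
        batch, n_ch, n_maps, length = x1.shape
        avg = x1.mean(axis=2)                                # (B, C, L)
        idx = x1.argmax(axis=2)
        mx = np.take_along_axis(x1, idx[:, :, None, :], axis=2)[:, :, 0, :]
        pooled = np.stack([avg, mx], axis=1)                 # (B, 2, C, L)
        k = self.k
        left = (k - 1) // 2
        right = k - 1 - left
        pp = np.pad(pooled, [(0, 0), (0, 0), (left, right), (0, 0)])
        pre = np.full((batch, n_ch, length), self.sb.value[0], dtype=x1.dtype)
        for t in range(k):
            pre += np.einsum("bpcl,p->bcl", pp[:, :, t:t + n_ch, :],
                             self.sw.value[:, t], optimize=True)
        gate = sigmoid(pre)
        self._cache = (x1, pooled, pp, idx, gate, left)
        return x1 * gate[:, :, None, :]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x1, pooled, pp, idx, gate, left = self._cache
        batch, n_ch, n_maps, length = x1.shape
        k = self.k
        dx1 = grad_out * gate[:, :, None, :]
        dgate = (grad_out * x1).sum(axis=2)                  # (B, C, L)
        dpre = dgate * gate * (1.0 - gate)
        self.sb.grad += dpre.sum()
        dpp = np.zeros_like(pp)
        for t in range(k):
            seg = pp[:, :, t:t + n_ch, :]                    # (B, 2, C, L)
            self.sw.grad[:, t] += np.einsum("bpcl,bcl->p", seg, dpre, optimize=True)
            dpp[:, :, t:t + n_ch, :] += np.einsum(
                "bcl,p->bpcl", dpre, self.sw.value[:, t], optimize=True)
        dpooled = dpp[:, :, left:left + n_ch, :]
        dx1 += dpooled[:, 0, :, None, :] / n_maps            # avg-pool branch
        scatter = np.zeros_like(x1)
        np.put_along_axis(scatter, idx[:, :, None, :], dpooled[:, 1, :, None, :], axis=2)
        dx1 += scatter
        return self.channel.backward(dx1)
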