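"""GDNet architecture assembly and the ablation variant builders.

The network stacks, in order:

1. a regular temporal convolution (1x17, 64 maps, stride 1, SAME padding,
   batch norm, linear activation) producing a ``(C, M, L)`` feature cube;
2. four group depth-wise convolution blocks (per-EEG-channel 1x17 kernels,
   stride 2, SAME padding, bias, LeakyReLU, batch norm), each optionally
   followed by the two-stage EEG attention module;
3. a depth-wise separable head: a Cx1 spatial convolution collapsing the
   electrode dimension (VALID, ELU) then a 1x1 point-wise convolution down
   to 16 maps (batch norm, ELU, dropout);
4. a single dense layer with identity activation feeding a softmax.

There are no pooling layers anywhere; temporal resolution is reduced only
by the stride-2 blocks, so the feature length follows the ceil-division
chain ``L -> ceil(L/2) -> ...`` (250 -> 125 -> 63 -> 32 -> 16).
Dropout (rate 0.5) appears exactly twice: after the group-block stack and
after the point-wise layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .attention import CBAMLayer, EEGAttentionLayer

VARIANTS = ("full", "model1", "model2", "model3", "model4", "model5", "model6")


@dataclass(frozen=True)
class GDNetConfig:
    """Architecture hyperparameters.

    ``n_feature_maps``, ``kernel_length``, ``n_group_blocks``,
    ``dropout_rate`` and ``pointwise_maps`` default to the published
    setting (64 maps, 1x17 kernels, 4 blocks, 0.5, 16).
    """

    n_channels: int
    n_samples: int
    n_classes: int = 40
    n_feature_maps: int = 64
    kernel_length: int = 17
    n_group_blocks: int = 4
    temporal_stride: int = 2
    dropout_rate: float = 0.5
    pointwise_maps: int = 16
    leaky_slope: float = 0.01
    attention_enabled: bool = True
    channel_attention_enabled: bool = True
    network_attention_enabled: bool = True
    attention_reduction: int = 8
    attention_shared: bool = False      # share attention params across blocks?
    cbam: bool = False                  # replace EEG attention with CBAM
    variant_id: str = "full"

    def __post_init__(self):
        if self.n_group_blocks < 1 or self.n_feature_maps < 1:
            raise ValueError("need at least one group block and one feature map")
        if self.variant_id not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant_id!r}")
        if self.cbam and not self.attention_enabled:
            raise ValueError("cbam=True requires attention_enabled=True")

    @property
    def feature_length(self) -> int:
        return nn.output_length_after_blocks(
            self.n_samples, self.n_group_blocks, self.temporal_stride)


class GDNet:
    """An assembled network plus its configuration.

    ``forward`` returns class probabilities; training utilities live in
    :mod:`gdnet.training`.
    """

    def __init__(self, cfg: GDNetConfig, network: nn.Network):
        self.cfg = cfg
        self.network = network

    # -- inference ----------------------------------------------------------
    def logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.network.forward(X, training=training)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.logits(X).argmax(axis=1)

    # -- bookkeeping --------------------------------------------------------
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.network.parameters().values())

    def architecture_summary(self) -> list[dict]:
        """Per-stage output shapes in (C, L, M) Table convention plus
        parameter counts; serialisable as JSON."""
        cfg = self.cfg
        rows = [{"layer": "input", "output_shape": [cfg.n_channels, cfg.n_samples],
                 "n_params": 0}]
        length = cfg.n_samples
        for layer in self.network.layers:
            n_params = sum(p.value.size for p in layer.parameters())
            name = type(layer).__name__
            if isinstance(layer, (nn.GroupDepthwiseConv, nn.RegularConv)):
                length = -(-length // layer.stride)
                shape = [cfg.n_channels, length, layer.out_maps]
            elif isinstance(layer, nn.TemporalConv):
                shape = [cfg.n_channels, length, layer.n_maps]
            elif isinstance(layer, nn.DepthwiseSpatialConv):
                shape = [1, length, layer.n_maps]
            elif isinstance(layer, nn.PointwiseConv):
                shape = [1, length, layer.out_maps]
            elif isinstance(layer, nn.Flatten):
                shape = [length * cfg.pointwise_maps]
            elif isinstance(layer, nn.Dense):
                shape = [layer.n_out]
            else:
                shape = rows[-1]["output_shape"]
            rows.append({"layer": name, "output_shape": shape, "n_params": n_params})
        return rows

    def summary_json(self) -> str:
        return json.dumps(self.architecture_summary(), indent=2)

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the embedded config."""
        state = self.network.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @staticmethod
    def load(path) -> "GDNet":
        with np.load(path) as data:
            cfg = GDNetConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = build_model(cfg)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.network.load_state_dict(state)
        return model


def _attention_layer(cfg: GDNetConfig, shared: EEGAttentionLayer | CBAMLayer | None):
    if not cfg.attention_enabled:
        return None
    if not (cfg.channel_attention_enabled or cfg.network_attention_enabled):
        return None
    if cfg.attention_shared and shared is not None:
        return shared
    if cfg.cbam:
        return CBAMLayer(cfg.n_feature_maps, reduction=cfg.attention_reduction,
                         spatial_kernel=7)
    return EEGAttentionLayer(
        cfg.n_feature_maps, reduction=cfg.attention_reduction,
        channel_stage=cfg.channel_attention_enabled,
        network_stage=cfg.network_attention_enabled)


def build_model(cfg: GDNetConfig) -> GDNet:
    """Assemble the network described by ``cfg``.

    Attention (when enabled) is inserted after every group block, so the
    refined cube is what the next block consumes; a ``cfg.attention_shared``
    switch reuses one set of attention parameters across blocks instead.
    """
    if cfg.n_channels < 1 or cfg.n_samples < 1:
        raise ValueError("n_channels and n_samples must be positive")
    K, k = cfg.n_feature_maps, cfg.kernel_length
    layers: list[nn.Layer] = [
        nn.TemporalConv(K, kernel=k),
        nn.BatchNorm(K),
    ]
    shared_attn = None
    for _ in range(cfg.n_group_blocks):
        if cfg.variant_id == "model1":
            layers.append(nn.RegularConv(K, K, kernel=k, stride=cfg.temporal_stride))
        else:
            layers.append(nn.GroupDepthwiseConv(
                cfg.n_channels, K, K, kernel=k, stride=cfg.temporal_stride))
        layers.append(nn.LeakyReLU(cfg.leaky_slope))
        layers.append(nn.BatchNorm(K))
        attn = _attention_layer(cfg, shared_attn)
        if attn is not None:
            if cfg.attention_shared and shared_attn is None:
                shared_attn = attn
            layers.append(attn)
    layers.append(nn.Dropout(cfg.dropout_rate))
    layers.append(nn.DepthwiseSpatialConv(cfg.n_channels, K))
    layers.append(nn.ELU())
    layers.append(nn.PointwiseConv(K, cfg.pointwise_maps))
    layers.append(nn.BatchNorm(cfg.pointwise_maps))
    layers.append(nn.ELU())
    layers.append(nn.Dropout(cfg.dropout_rate))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(cfg.feature_length * cfg.pointwise_maps, cfg.n_classes))
    return GDNet(cfg, nn.Network(layers))


def build_variant(variant_id: str, base_cfg: GDNetConfig) -> GDNet:
    """Ablation variants:

    * ``model1`` — group depth-wise filters replaced by regular 2D
      convolutions of equal kernel size and stride (shared across channels);
    * ``model2`` — shallow version with two group blocks;
    * ``model3`` — EEG attention removed entirely;
    * ``model4`` — channel-wise attention removed (network stage kept);
    * ``model5`` — network-wise attention removed (channel stage kept);
    * ``model6`` — EEG attention replaced by a CBAM block.
    """
    if variant_id == "full":
        cfg = replace(base_cfg, variant_id="full")
    elif variant_id == "model1":
        cfg = replace(base_cfg, variant_id="model1")
    elif variant_id == "model2":
        cfg = replace(base_cfg, variant_id="model2", n_group_blocks=2)
    elif variant_id == "model3":
        cfg = replace(base_cfg, variant_id="model3", attention_enabled=False)
    elif variant_id == "model4":
        cfg = replace(base_cfg, variant_id="model4", channel_attention_enabled=False)
    elif variant_id == "model5":
        cfg = replace(base_cfg, variant_id="model5", network_attention_enabled=False)
    elif variant_id == "model6":
        cfg = replace(base_cfg, variant_id="model6", cbam=True)
    else:
        raise ValueError(f"unknown variant {variant_id!r}")
    return build_model(cfg)
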