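"""3D residual U-Net with attention-gated skips and switchable normalization.

Architecture (fully convolutional, channel-first, implicit batch of 1):

* encoder: a stem 3x3x3 convolution to ``base_channels``, then per level a
  pre-norm residual block (two 3x3x3 convolutions, identity shortcut)
  followed by a stride-2 kernel-2 convolution that doubles the channels;
* bottleneck: one residual block;
* decoder: per level a kernel-2 stride-2 transposed convolution halving the
  channels, an additive attention gate on the encoder skip, additive
  combination, and a residual block;
* head: 1x1x1 convolution to ``n_classes`` followed by a channel softmax.

The attention gate follows the additive 2D mechanism lifted to 3D: the
skip is brought to the gating (coarser) resolution by a stride-2
convolution, combined additively with a 1x1x1 projection of the gating
signal, passed through ReLU, projected to a single channel, squashed by a
sigmoid, trilinearly upsampled, and multiplied onto the skip — per-voxel
multiplicative attention coefficients in [0, 1].

Every normalization site is switchable normalization: a learnable
softmax-weighted convex mixture of instance, layer and batch statistics
(with batch size 1 the batch statistics coincide with instance statistics,
but the mixture parametrization is kept).

Channel widths double per level (base_channels x 2^level); block counts,
widths and activations are configuration knobs, not fidelity claims.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _autograd as ag

__all__ = ["ModelConfig", "SegmentationModel", "build_model",
           "forward", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    depth: int = 4            # resolution levels (depth-1 downsamplings)
    base_channels: int = 8
    n_classes: int = 8        # BG + DG/CA1/CA2/CA3/SUB (+ HEAD/TAIL)
    norm: str = "switch"      # 'switch' | 'instance'
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel configuration")
        if self.norm not in ("switch", "instance"):
            raise ValueError(f"unknown norm {self.norm!r}")

    @property
    def divisor(self):
        """Required divisor of every input dimension."""
        return 2 ** (self.depth - 1)


# ---------------------------------------------------------------------------
# layers


class _SwitchNorm:
    """Learnable convex mixture of instance / layer / batch statistics."""

    EPS = 1e-5

    def __init__(self, channels, store, prefix, mode="switch"):
        self.mode = mode
        self.gain = store.add(f"{prefix}.gain", np.ones((channels, 1, 1, 1)))
        self.bias = store.add(f"{prefix}.bias", np.zeros((channels, 1, 1, 1)))
        if mode == "switch":
            self.mean_logits = store.add(f"{prefix}.mean_logits", np.zeros(3))
            self.var_logits = store.add(f"{prefix}.var_logits", np.zeros(3))

    def mixture_weights(self):
        """(mean weights, variance weights); each sums to 1 by construction."""
        wm = ag.softmax(self.mean_logits, axis=0)
        wv = ag.softmax(self.var_logits, axis=0)
        return wm, wv

    def __call__(self, x):
        if self.mode == "instance":
            mu = x.mean(axis=(1, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(1, 2, 3), keepdims=True)
            return self.gain * ((x - mu) / (var + self.EPS).sqrt()) + self.bias
        return ag.switch_norm(x, self.gain, self.bias,
                              self.mean_logits, self.var_logits, eps=self.EPS)


class _ParamStore:
    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, ag.Tensor] = {}

    def add(self, name, value):
        t = ag.parameter(np.asarray(value, dtype=np.float32))
        self.params[name] = t
        return t

    def conv(self, name, shape, fan_in):
        w = self.rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        return self.add(name, w)


class _ResBlock:
    """Pre-norm residual block: x + conv(relu(norm(conv(relu(norm(x))))))."""

    def __init__(self, channels, store, prefix, norm):
        self.n1 = _SwitchNorm(channels, store, f"{prefix}.norm1", norm)
        self.w1 = store.conv(f"{prefix}.conv1.weight",
                             (channels, channels, 3, 3, 3), channels * 27)
        self.n2 = _SwitchNorm(channels, store, f"{prefix}.norm2", norm)
        self.w2 = store.conv(f"{prefix}.conv2.weight",
                             (channels, channels, 3, 3, 3), channels * 27)

    def __call__(self, x):
        h = ag.conv3x3(ag.relu(self.n1(x)), self.w1)
        h = ag.conv3x3(ag.relu(self.n2(h)), self.w2)
        return x + h


class _AttentionGate:
    """Additive attention gate producing per-voxel coefficients in [0, 1]."""

    def __init__(self, skip_ch, gate_ch, store, prefix):
        inter = max(skip_ch // 2, 1)
        self.w_x = store.conv(f"{prefix}.theta_x.weight",
                              (inter, skip_ch, 2, 2, 2), skip_ch * 8)
        self.w_g = store.conv(f"{prefix}.phi_g.weight", (inter, gate_ch), gate_ch)
        self.w_psi = store.conv(f"{prefix}.psi.weight", (1, inter), inter)
        self.psi_bias = store.add(f"{prefix}.psi.bias", np.zeros((1, 1, 1, 1)))
        self.last_coefficients = None

    def __call__(self, skip, gate):
        q = ag.down2(skip, self.w_x) + ag.conv1x1(gate, self.w_g)
        q = ag.conv1x1(ag.relu(q), self.w_psi) + self.psi_bias
        alpha = ag.upsample2_linear(ag.sigmoid(q))
        self.last_coefficients = alpha.data
        return skip * alpha


class SegmentationModel:
    """Maps a single-channel 3D crop to an n_classes probability map."""

    def __init__(self, config: ModelConfig):
        self.config = config
        store = _ParamStore(config.seed)
        ch = config.base_channels
        depth = config.depth

        self.stem = store.conv("stem.weight", (ch, 1, 3, 3, 3), 27)
        self.enc_blocks, self.downs = [], []
        for lvl in range(depth - 1):
            c = ch * 2 ** lvl
            self.enc_blocks.append(_ResBlock(c, store, f"enc{lvl}", config.norm))
            self.downs.append(store.conv(f"down{lvl}.weight",
                                         (2 * c, c, 2, 2, 2), c * 8))
        cb = ch * 2 ** (depth - 1)
        self.bottleneck = _ResBlock(cb, store, "bottleneck", config.norm)

        self.ups, self.gates, self.dec_blocks = [], [], []
        for lvl in reversed(range(depth - 1)):
            c = ch * 2 ** lvl
            self.ups.append(store.conv(f"up{lvl}.weight", (2 * c, c, 2, 2, 2),
                                       2 * c * 8))
            self.gates.append(_AttentionGate(c, 2 * c, store, f"gate{lvl}"))
            self.dec_blocks.append(_ResBlock(c, store, f"dec{lvl}", config.norm))

        self.head_w = store.conv("head.weight", (config.n_classes, ch), ch)
        self.head_b = store.add("head.bias",
                                np.zeros((config.n_classes, 1, 1, 1)))
        self.params = store.params

    # -- forward -----------------------------------------------------------

    def logits(self, crop):
        x = crop.data if isinstance(crop, ag.Tensor) else np.asarray(crop)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected a single-channel 3D crop, got {x.shape}")
        d = self.config.divisor
        if any(s % d for s in x.shape[1:]):
            raise ValueError(f"input shape {x.shape[1:]} not divisible by "
                             f"{d} (pad upstream)")

        h = ag.conv3x3(ag.constant(x.astype(np.float32)), self.stem)
        skips = []
        for block, down in zip(self.enc_blocks, self.downs):
            h = block(h)
            skips.append(h)
            h = ag.down2(h, down)
        h = self.bottleneck(h)
        for up, gate, block, skip in zip(self.ups, self.gates,
                                         self.dec_blocks, reversed(skips)):
            gated = gate(skip, h)
            h = ag.up2(h, up) + gated
            h = block(h)
        return ag.conv1x1(h, self.head_w) + self.head_b

    def forward(self, crop):
        """Per-voxel class probabilities, shape (n_classes, D, H, W)."""
        return ag.softmax(self.logits(crop), axis=0)

    def predict(self, crop):
        """Argmax label map (evaluation mode, deterministic)."""
        return np.argmax(self.forward(crop).data, axis=0).astype(np.int16)

    # -- parameters --------------------------------------------------------

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        missing = set(self.params) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch for parameters: {sorted(missing)}")
        for k, v in state.items():
            if self.params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def prunable_parameters(self):
        """Convolution weights (norm gains/biases and biases excluded)."""
        return {k: v for k, v in self.params.items() if k.endswith(".weight")
                or k in ("stem.weight",)}

    def attention_coefficients(self):
        return [g.last_coefficients for g in self.gates]

    def n_parameters(self):
        return int(sum(v.data.size for v in self.params.values()))


def build_model(config: ModelConfig) -> SegmentationModel:
    return SegmentationModel(config)


def forward(model: SegmentationModel, crop):
    return model.forward(crop)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: SegmentationModel, extra=None):
    state = model.state_dict()
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **{k: v for k, v in state.items()})


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = SegmentationModel(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model
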