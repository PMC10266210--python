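"""Network architecture for cross-dataset fatigue regression.

The shared feature extractor is a 1-D residual CNN with CBAM-style
channel/spatial attention after each residual block, followed by a GRU that
reads the final feature map as a temporal sequence and emits its last hidden
state as the segment feature vector.  Three heads sit on top of the
extractor:

* a domain discriminator (single logit) used by the self-supervised pretext
  task that tells the two datasets apart,
* one or more alignment projections (64-unit MLPs by default) whose outputs
  feed the MMD term during domain adaptation,
* a one-node regression MLP that predicts the continuous fatigue index.

``backbone_depth`` selects ``resnet50`` (the full-scale default
architecture), ``resnet18``, or ``tiny`` (two residual blocks, <200k
parameters) for CPU-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, concat
from .nn.layers import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    GRU,
    Linear,
    Module,
    ReLU,
    Sequential,
)

__all__ = [
    "ModelSpec",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "FatigueNet",
    "build_model",
    "channel_attention",
    "spatial_attention",
    "forward_features",
    "discriminate_domain",
    "project_alignment",
    "regress_index",
]

_DEPTHS = ("tiny", "resnet18", "resnet50")


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    Defaults mirror the full-scale configuration (ResNet50 backbone, GRU with
    a single 64-unit hidden layer, 64-dimensional alignment projection,
    dropout 0.25); ``tiny`` is the desk-scale depth used in tests.
    """

    backbone_depth: str = "resnet50"
    in_channels: int = 17
    use_attention: bool = True
    use_gru: bool = True
    gru_hidden: int = 64
    gru_layers: int = 1
    align_dim: int = 64
    align_heads: int = 1
    dropout: float = 0.25
    attention_reduction: int = 16

    def __post_init__(self) -> None:
        if self.backbone_depth not in _DEPTHS:
            raise ValueError(f"backbone_depth must be one of {_DEPTHS}")
        if self.gru_hidden <= 0 or self.align_dim <= 0:
            raise ValueError("gru_hidden and align_dim must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.align_heads < 1:
            raise ValueError("align_heads must be >= 1")


class ChannelAttention(Module):
    """Squeeze channel descriptors (avg + max pool over time) through a shared
    bottleneck MLP; sigmoid of the sum gives per-channel weights in (0, 1)."""

    def __init__(self, n_ch: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, n_ch // reduction)
        self.fc1 = Linear(n_ch, hidden, rng)
        self.fc2 = Linear(hidden, n_ch, rng)
        self.force_identity = False  # diagnostic: weights forced to 1

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=2)  # (B, C)
        mx = x.max(axis=2)
        s = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return s.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.force_identity:
            return x
        w = self.weights(x)
        return x * w.reshape(w.shape[0], w.shape[1], 1)


class SpatialAttention(Module):
    """Channel-pooled (avg + max) maps through a 1-D conv; sigmoid gives
    per-time-step weights in (0, 1)."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv1d(2, 1, kernel, rng, padding=kernel // 2)
        self.force_identity = False

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)  # (B, 1, L)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.force_identity:
            return x
        return x * self.weights(x)


class CBAM(Module):
    def __init__(self, n_ch: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(n_ch, reduction, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


def _gabor_bank(rng: np.random.Generator, out_ch: int, in_ch: int, kernel: int,
                fs: float = 128.0, f_lo: float = 2.0, f_hi: float = 40.0) -> np.ndarray:
    """Initialize a conv stem as a bank of modulated-Gaussian (Gabor) band
    filters at log-spaced center frequencies with random spatial mixing.

    The filters stay fully trainable; the initialization only ensures the
    network starts with band-selective temporal filters, without which
    band-power structure is invisible to a randomly initialized stem.
    """
    t = (np.arange(kernel) - (kernel - 1) / 2) / fs
    freqs = np.geomspace(f_lo, f_hi, out_ch)
    weights = np.zeros((out_ch, in_ch, kernel))
    for o, f in enumerate(freqs):
        envelope = np.exp(-0.5 * (t / (1.2 / f)) ** 2)
        g = envelope * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        g /= np.linalg.norm(g)
        mix = rng.normal(size=in_ch)
        mix /= np.linalg.norm(mix)
        weights[o] = np.outer(mix, g)
    return weights


class SpectralStem(Module):
    """Learned filter bank followed by instantaneous power: conv (Gabor
    init, stride 2) -> square -> overlapped average pooling (250 ms windows,
    125 ms hop) -> log -> batch norm.

    The output is a log-band-power sequence — a learned spectrogram — which
    is the representation the residual stages and the GRU operate on.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 33, eps: float = 1e-5):
        super().__init__()
        self.conv = Conv1d(in_ch, out_ch, kernel, rng, stride=2, bias=False)
        self.conv.weight.data = _gabor_bank(rng, out_ch, in_ch, kernel)
        self.bn = BatchNorm1d(out_ch)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        h = h * h
        B, C, L = h.shape
        nbins = L // 8
        bins = h[:, :, : nbins * 8].reshape(B, C, nbins, 8).mean(axis=3)
        # overlapped 16-sample windows at stride 8 = mean of adjacent bins
        pooled = (bins[:, :, :-1] + bins[:, :, 1:]) * 0.5
        return self.bn((pooled + self.eps).log())


class BasicBlock(Module):
    """Two 3-tap convolutions with a skip connection; CBAM (when enabled) is
    applied to the residual branch before the addition."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, spec: ModelSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(in_ch, out_ch, 3, rng, stride=stride, bias=False)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, 3, rng, bias=False)
        self.bn2 = BatchNorm1d(out_ch)
        self.attn = CBAM(out_ch, spec.attention_reduction, rng) if spec.use_attention else None
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(
                Conv1d(in_ch, out_ch, 1, rng, stride=stride, padding=0, bias=False),
                BatchNorm1d(out_ch),
            )
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.attn is not None:
            out = self.attn(out)
        skip = self.down(x) if self.down is not None else x
        return (out + skip).relu()


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 bottleneck with expansion 4 (ResNet50-style)."""

    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int, spec: ModelSpec,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv1d(in_ch, mid_ch, 1, rng, padding=0, bias=False)
        self.bn1 = BatchNorm1d(mid_ch)
        self.conv2 = Conv1d(mid_ch, mid_ch, 3, rng, stride=stride, bias=False)
        self.bn2 = BatchNorm1d(mid_ch)
        self.conv3 = Conv1d(mid_ch, out_ch, 1, rng, padding=0, bias=False)
        self.bn3 = BatchNorm1d(out_ch)
        self.attn = CBAM(out_ch, spec.attention_reduction, rng) if spec.use_attention else None
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(
                Conv1d(in_ch, out_ch, 1, rng, stride=stride, padding=0, bias=False),
                BatchNorm1d(out_ch),
            )
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        if self.attn is not None:
            out = self.attn(out)
        skip = self.down(x) if self.down is not None else x
        return (out + skip).relu()


class Backbone(Module):
    """Stem convolution plus residual stages; emits a (B, C', L') map."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        depth = spec.backbone_depth
        if depth == "tiny":
            stem_ch = 16
            plan = [(16, 2, 1, BasicBlock), (32, 2, 1, BasicBlock)]
        elif depth == "resnet18":
            stem_ch = 64
            plan = [(64, 1, 2, BasicBlock), (128, 2, 2, BasicBlock),
                    (256, 2, 2, BasicBlock), (512, 2, 2, BasicBlock)]
        else:  # resnet50
            stem_ch = 64
            plan = [(64, 1, 3, Bottleneck), (128, 2, 4, Bottleneck),
                    (256, 2, 6, Bottleneck), (512, 2, 3, Bottleneck)]
        self.seq_pool = 1
        self.stem = SpectralStem(spec.in_channels, stem_ch, rng)
        blocks: list[Module] = []
        ch = stem_ch
        for width, stride, n_blocks, cls in plan:
            for b in range(n_blocks):
                blocks.append(cls(ch, width, stride if b == 0 else 1, spec, rng))
                ch = width * getattr(cls, "expansion", 1)
        self.blocks = blocks
        self.out_channels = ch

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for block in self.blocks:
            x = block(x)
        return x


class FeatureExtractor(Module):
    """Backbone + GRU (or global average pooling when the GRU is ablated)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.backbone = Backbone(spec, rng)
        if spec.use_gru:
            self.gru = GRU(self.backbone.out_channels, spec.gru_hidden, rng,
                           n_layers=spec.gru_layers)
            self.feature_dim = spec.gru_hidden
        else:
            self.gru = None
            self.feature_dim = self.backbone.out_channels

    def forward(self, x: Tensor) -> Tensor:
        fmap = self.backbone(x)  # (B, C', L')
        pool = self.backbone.seq_pool
        if pool > 1:
            B, C, L = fmap.shape
            L2 = (L // pool) * pool
            fmap = fmap[:, :, :L2].reshape(B, C, L2 // pool, pool).mean(axis=3)
        if self.gru is None:
            return fmap.mean(axis=2)
        return self.gru(fmap.transpose(0, 2, 1))


class FatigueNet(Module):
    """Feature extractor plus domain-discriminator, alignment and regression
    heads.  Dropout (rate from the spec) precedes every head."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        self.extractor = FeatureExtractor(spec, rng)
        d = self.extractor.feature_dim
        self.drop = Dropout(spec.dropout, np.random.default_rng(rng.integers(2**31)))
        self.disc_head = Sequential(Linear(d, 32, rng), ReLU(), Linear(32, 1, rng))
        self.align_nets = [
            Sequential(Linear(d, spec.align_dim, rng), ReLU(),
                       Linear(spec.align_dim, spec.align_dim, rng))
            for _ in range(spec.align_heads)
        ]
        self.reg_head = Linear(d, 1, rng)  # single-layer, one node

    # -- pipeline stages ------------------------------------------------------
    def features(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 3 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected batch x {self.spec.in_channels} x T input, got {x.shape}"
            )
        return self.extractor(x)

    def discriminate(self, feats: Tensor) -> Tensor:
        """Probability that each row comes from the target domain."""
        return self.disc_head(self.drop(feats)).sigmoid().reshape(-1)

    def align(self, feats: Tensor) -> list[Tensor]:
        h = self.drop(feats)
        return [net(h) for net in self.align_nets]

    def regress(self, feats: Tensor) -> Tensor:
        """Unclipped fatigue-index prediction (clip at evaluation only)."""
        return self.reg_head(self.drop(feats)).reshape(-1)

    # -- diagnostics -----------------------------------------------------------
    def force_attention_identity(self, value: bool = True) -> None:
        for block in self.extractor.backbone.blocks:
            if getattr(block, "attn", None) is not None:
                block.attn.channel.force_identity = value
                block.attn.spatial.force_identity = value


def build_model(spec: ModelSpec, seed: int = 0) -> FatigueNet:
    """Construct a :class:`FatigueNet` with seed-determined initialization."""
    return FatigueNet(spec, np.random.default_rng(seed))


def save_checkpoint(model: FatigueNet, path) -> None:
    """Checkpoint = JSON spec header + named weight arrays in one .npz."""
    import dataclasses
    import json

    header = json.dumps(dataclasses.asdict(model.spec))
    state = model.state_dict()
    np.savez_compressed(path, __spec__=header, **state)


def load_checkpoint(path) -> FatigueNet:
    import json

    with np.load(path, allow_pickle=False) as npz:
        spec = ModelSpec(**json.loads(str(npz["__spec__"])))
        state = {k: npz[k] for k in npz.files if k != "__spec__"}
    model = build_model(spec, seed=0)
    model.load_state_dict(state)
    return model


# -- functional surface -------------------------------------------------------

def channel_attention(fmap: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Per-channel attention weights in (0, 1) for a (B, C, L) feature map."""
    return module.weights(Tensor(np.asarray(fmap, dtype=float))).data


def spatial_attention(fmap: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Per-position attention weights in (0, 1), shape (B, 1, L)."""
    return module.weights(Tensor(np.asarray(fmap, dtype=float))).data


def forward_features(seg_batch: np.ndarray, model: FatigueNet) -> np.ndarray:
    """Feature vectors (batch x feature_dim) for a batch of segments."""
    model.eval()
    return model.features(np.asarray(seg_batch, dtype=float)).data


def discriminate_domain(features: np.ndarray, model: FatigueNet) -> np.ndarray:
    """P(target) per feature row."""
    model.eval()
    return model.discriminate(Tensor(np.asarray(features, dtype=float))).data


def project_alignment(features: np.ndarray, model: FatigueNet) -> np.ndarray:
    """First alignment-head projection (batch x align_dim)."""
    model.eval()
    return model.align(Tensor(np.asarray(features, dtype=float)))[0].data


def regress_index(features: np.ndarray, model: FatigueNet, *, clip: bool = True) -> np.ndarray:
    """Fatigue-index predictions; clipped to [0, 1] for evaluation."""
    model.eval()
    pred = model.regress(Tensor(np.asarray(features, dtype=float))).data
    return np.clip(pred, 0.0, 1.0) if clip else pred
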