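"""Single-view and mid-fusion multiview video classification models.

The multiview architecture passes each view's clip through its own
(non-weight-shared) five-block trunk, stacks the per-view embeddings
along a new view axis V, and fuses them with two further
conv-batchnorm-ReLU blocks:

    stack    -> (B, C, V, T, H, W)
    flatten  -> (B, C, V, THW)        2D conv over (view, spatiotemporal)
    reshape  -> (B, CT, V, H, W)      3D conv over (view, height, width),
                                      expanding channels x expansion_factor
    reshape  -> (B, CV, T, H, W)
    mean-pool over (T, H, W), fully connected layer, decision head.

At full scale (three 64x224x224x3 clips through X3D-M trunks,
expansion 128) the full model has ~230M trainable parameters; a ``tiny``
preset runs the identical shape algebra on CPU in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, x3d
from .errors import ConfigurationError

# Fusion free knobs frozen in the default configuration: with the
# bottleneck width below and 3x3(-x3) fusion kernels, the full-scale
# model totals 232.5M parameters (230M at ten-million precision).
FULL_SCALE_FUSION_CHANNELS = 4
FULL_SCALE_EXPANSION_FACTOR = 128


@dataclass(frozen=True)
class BackboneConfig:
    """Per-view trunk configuration.

    ``tiny`` is a five-block plain conv-BN-ReLU trunk for CPU-scale
    experiments; ``x3d_m`` is the full X3D-Medium trunk.
    """

    preset: str = "tiny"
    clip_length: int = 16
    side: int = 32
    in_channels: int = 3
    # tiny preset knobs
    widths: tuple[int, ...] = (8, 12, 16, 24, 24)
    strides: tuple[tuple[int, int, int], ...] = (
        (1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (1, 1, 1))

    def __post_init__(self):
        if self.preset not in ("tiny", "x3d_m"):
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if self.preset == "tiny" and len(self.widths) != len(self.strides):
            raise ConfigurationError("widths and strides must align")
        t, h = self.clip_length, self.side
        for st in self.spatial_strides():
            if h % st:
                raise ConfigurationError(
                    f"side {self.side} not divisible by stage strides")
            h //= st
        for st in self.temporal_strides():
            if t % st:
                raise ConfigurationError(
                    f"clip_length {self.clip_length} not divisible by "
                    "temporal strides")
            t //= st

    def spatial_strides(self) -> tuple[int, ...]:
        if self.preset == "x3d_m":
            return (2, 2, 2, 2, 2)
        return tuple(s[1] for s in self.strides)

    def temporal_strides(self) -> tuple[int, ...]:
        if self.preset == "x3d_m":
            return (1,) * 5
        return tuple(s[0] for s in self.strides)

    def embedding_shape(self) -> tuple[int, int, int, int]:
        """(C, T', H', W') of the trunk output for one clip."""
        if self.preset == "x3d_m":
            return x3d.x3d_m_embedding_shape(self.clip_length, self.side)
        t, h = self.clip_length, self.side
        for st in self.strides:
            t //= st[0]
            h //= st[1]
        return (self.widths[-1], t, h, h)


def full_scale_backbone_config() -> BackboneConfig:
    """X3D-M on the reference input size: 64-frame, 224-pixel clips."""
    return BackboneConfig(preset="x3d_m", clip_length=64, side=224)


@dataclass(frozen=True)
class MultiviewConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    n_views: int = 3
    fusion_channels: int = 8            # conv-6 output width (C6)
    expansion_factor: int = 8           # conv-7 channel expansion
    head: str = "sigmoid_binary"
    n_classes: int = 1

    def __post_init__(self):
        if self.n_views < 2:
            raise ConfigurationError("multiview model needs n_views >= 2")
        if self.expansion_factor < 1:
            raise ConfigurationError("expansion_factor must be >= 1")
        if self.head not in ("sigmoid_binary", "softmax_multiclass"):
            raise ConfigurationError(f"unknown head {self.head!r}")


def full_scale_multiview_config() -> MultiviewConfig:
    return MultiviewConfig(backbone=full_scale_backbone_config(),
                           fusion_channels=FULL_SCALE_FUSION_CHANNELS,
                           expansion_factor=FULL_SCALE_EXPANSION_FACTOR)


def _tiny_trunk(config: BackboneConfig) -> nn.Sequential:
    layers: list[nn.Module] = []
    c_in = config.in_channels
    for width, stride in zip(config.widths, config.strides):
        layers += [nn.Conv(c_in, width, 3, stride=stride, padding=1),
                   nn.BatchNorm(width), nn.ReLU()]
        c_in = width
    return nn.Sequential(*layers)


def build_backbone(config: BackboneConfig) -> nn.Module:
    """The trunk only (five convolutional blocks, no head)."""
    if config.preset == "x3d_m":
        return x3d.build_x3d_m_trunk(config.in_channels)
    return _tiny_trunk(config)


class ClassifierHead(nn.Module):
    """Global average pool plus a fully connected decision layer.

    ``forward`` returns raw logits; use :meth:`scores` (or the model's
    ``forward``) for calibrated outputs in [0, 1].
    """

    def __init__(self, in_features: int, n_classes: int):
        super().__init__()
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_features, n_classes, bias=True)

    def forward(self, x):
        self._pooled_ndim = x.ndim
        return self.fc(self.pool(x))

    def backward(self, grad):
        return self.pool.backward(self.fc.backward(grad))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SingleViewModel(nn.Module):
    """Clip in, score out. Binary scores lie in [0, 1]; multiclass scores
    are a probability vector."""

    def __init__(self, config: BackboneConfig, head: str = "sigmoid_binary",
                 n_classes: int = 1):
        super().__init__()
        if head not in ("sigmoid_binary", "softmax_multiclass"):
            raise ConfigurationError(f"unknown head {head!r}")
        self.config = config
        self.head_kind = head
        self.trunk = build_backbone(config)
        c = config.embedding_shape()[0]
        self.head = ClassifierHead(c, n_classes)

    def _check_clip(self, x):
        expected = (self.config.in_channels, self.config.clip_length,
                    self.config.side, self.config.side)
        if x.ndim != 5 or x.shape[1:] != expected:
            raise ConfigurationError(
                f"clip shape {x.shape} does not match configured "
                f"(B, {', '.join(map(str, expected))})")

    def embed(self, x):
        self._check_clip(x)
        self.last_embedding = self.trunk(x)
        return self.last_embedding

    def forward_logits(self, x):
        return self.head(self.embed(x))

    def forward(self, x):
        logits = self.forward_logits(x)
        if self.head_kind == "sigmoid_binary":
            return _sigmoid(logits[:, 0] if logits.shape[1] == 1 else logits)
        return _softmax(logits)

    def backward_logits(self, grad):
        """Gradient from d(loss)/d(logits); also records the embedding
        gradient for grad-CAM."""
        self.last_embedding_grad = self.head.backward(grad)
        return self.trunk.backward(self.last_embedding_grad)


class FusionModule(nn.Module):
    """The two cross-view fusion blocks with their reshape algebra.

    Exposes ``intermediate_shapes`` after each forward pass, keyed by
    stage: stacked, flattened, block6, reshaped_ct, block7, reshaped_cv,
    pooled.
    """

    def __init__(self, emb_shape: tuple[int, int, int, int], n_views: int,
                 fusion_channels: int, expansion_factor: int):
        super().__init__()
        c, t, h, w = emb_shape
        self.emb_shape = emb_shape
        self.n_views = n_views
        self.c6 = fusion_channels
        self.expansion = expansion_factor
        self.conv6 = nn.Conv(c, self.c6, 3, padding=1, ndim=2)
        self.bn6 = nn.BatchNorm(self.c6)
        self.relu6 = nn.ReLU()
        c7_in = self.c6 * t
        self.conv7 = nn.Conv(c7_in, c7_in * expansion_factor, 3, padding=1, ndim=3)
        self.bn7 = nn.BatchNorm(c7_in * expansion_factor)
        self.relu7 = nn.ReLU()
        self.out_features = expansion_factor * self.c6 * n_views

    def forward(self, embeddings: list[np.ndarray]):
        if len(embeddings) != self.n_views:
            raise ConfigurationError(
                f"expected {self.n_views} view embeddings, got {len(embeddings)}")
        shapes = {e.shape for e in embeddings}
        if len(shapes) != 1:
            raise ConfigurationError(f"view embeddings disagree in shape: {shapes}")
        c, t, h, w = self.emb_shape
        if embeddings[0].shape[1:] != (c, t, h, w):
            raise ConfigurationError(
                f"embedding shape {embeddings[0].shape[1:]} does not match "
                f"configured {(c, t, h, w)}")
        b = embeddings[0].shape[0]
        v = self.n_views
        rec = {}
        x = np.stack(embeddings, axis=2)                    # (B, C, V, T, H, W)
        rec["stacked"] = x.shape
        x = x.reshape(b, c, v, t * h * w)                   # (B, C, V, THW)
        rec["flattened"] = x.shape
        x = self.relu6(self.bn6(self.conv6(x)))             # (B, C6, V, THW)
        rec["block6"] = x.shape
        # (B, C6, V, THW) -> (B, C6*T, V, H, W)
        x = (x.reshape(b, self.c6, v, t, h, w)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, self.c6 * t, v, h, w))
        rec["reshaped_ct"] = x.shape
        x = self.relu7(self.bn7(self.conv7(x)))             # (B, C6*T*E, V, H, W)
        rec["block7"] = x.shape
        # (B, (E*C6)*T, V, H, W) -> (B, (E*C6)*V, T, H, W)
        cpp = self.expansion * self.c6
        x = (x.reshape(b, cpp, t, v, h, w)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, cpp * v, t, h, w))
        rec["reshaped_cv"] = x.shape
        pooled = x.mean(axis=(2, 3, 4))                     # (B, E*C6*V)
        rec["pooled"] = pooled.shape
        self.intermediate_shapes = rec
        self._dims = (b, v)
        return pooled

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        b, v = self._dims
        c, t, h, w = self.emb_shape
        cpp = self.expansion * self.c6
        g = (np.broadcast_to(grad.reshape(b, cpp * v, 1, 1, 1),
                             (b, cpp * v, t, h, w)) / (t * h * w))
        g = (g.reshape(b, cpp, v, t, h, w)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, cpp * t, v, h, w))
        g = self.conv7.backward(self.bn7.backward(self.relu7.backward(g)))
        g = (g.reshape(b, self.c6, t, v, h, w)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, self.c6, v, t * h * w))
        g = self.conv6.backward(self.bn6.backward(self.relu6.backward(g)))
        g = g.reshape(b, c, v, t, h, w)
        return [np.ascontiguousarray(g[:, :, i]) for i in range(v)]


def fuse_views(embeddings: list[np.ndarray], fusion: FusionModule,
               return_intermediates: bool = False):
    """Apply the fusion blocks to per-view embeddings."""
    pooled = fusion(embeddings)
    if return_intermediates:
        return pooled, fusion.intermediate_shapes
    return pooled


class MultiviewModel(nn.Module):
    """Three clips in, one score out; per-view trunks are independently
    parameterized (no weight sharing across view slots)."""

    def __init__(self, config: MultiviewConfig):
        super().__init__()
        self.config = config
        self.trunks = [build_backbone(config.backbone)
                       for _ in range(config.n_views)]
        emb = config.backbone.embedding_shape()
        self.fusion = FusionModule(emb, config.n_views,
                                   config.fusion_channels,
                                   config.expansion_factor)
        self.fc = nn.Linear(self.fusion.out_features, config.n_classes, bias=True)

    def _check(self, clips):
        if len(clips) != self.config.n_views:
            missing = self.config.n_views - len(clips)
            raise ConfigurationError(
                f"expected {self.config.n_views} view clips, got {len(clips)} "
                f"({missing} view slot(s) missing)")

    def forward_logits(self, clips: list[np.ndarray]):
        self._check(clips)
        self.last_embeddings = [trunk(clip)
                                for trunk, clip in zip(self.trunks, clips)]
        pooled = self.fusion(self.last_embeddings)
        return self.fc(pooled)

    def forward(self, clips: list[np.ndarray]):
        logits = self.forward_logits(clips)
        if self.config.head == "sigmoid_binary":
            return _sigmoid(logits[:, 0] if logits.shape[1] == 1 else logits)
        return _softmax(logits)

    def backward_logits(self, grad):
        g = self.fc.backward(grad)
        self.last_embedding_grads = self.fusion.backward(g)
        return [trunk.backward(ge)
                for trunk, ge in zip(self.trunks, self.last_embedding_grads)]


def build_single_view_model(config: BackboneConfig, head: str = "sigmoid_binary",
                            n_classes: int = 1, seed: int = 0) -> SingleViewModel:
    model = SingleViewModel(config, head=head, n_classes=n_classes)
    model.initialize(np.random.default_rng([seed, 11]))
    return model


def build_multiview_model(config: MultiviewConfig, seed: int = 0) -> MultiviewModel:
    model = MultiviewModel(config)
    model.initialize(np.random.default_rng([seed, 13]))
    return model


def late_fusion_average(scores) -> np.ndarray | float:
    """Arithmetic mean of the single-view scores (the late-fusion
    comparator)."""
    arr = np.asarray(scores, dtype=np.float64)
    return arr.mean(axis=0)


def count_parameters(model: nn.Module) -> int:
    return model.n_parameters()
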