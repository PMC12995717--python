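"""X3D-Medium backbone: the per-view video trunk.

X3D ("Expand 3D") is a family of efficient 3D-convolutional video
networks built from channel-separated bottleneck blocks. The Medium
preset used here follows the published specification: a 24-channel
stem (1x3x3 spatial conv + 5x1x1 depthwise temporal conv), four
residual stages of depths 3/5/11/7 with output widths 24/48/96/192 and
bottleneck inner widths 2.25x (54/108/216/432), squeeze-excitation
(ratio 1/16) on every other block, swish inner activation, no temporal
downsampling, and 2x spatial downsampling per stage. The classifier
head projects 192 -> 432 -> 2048 -> classes; with the 400-class
reference head the full model has ~3.8M trainable parameters.

The trunk (stem + 4 stages, the "first five convolutional blocks") is
what the multiview architecture uses per view; its embedding for a
(3, T, S, S) clip has shape (192, T, S/32, S/32).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError

# (depth, dim_out, dim_inner) per residual stage; inner = 2.25 * out
X3D_M_STAGES = ((3, 24, 54), (5, 48, 108), (11, 96, 216), (7, 192, 432))
X3D_STEM_CHANNELS = 24
X3D_EMBED_CHANNELS = 192
X3D_HEAD_INNER = 432
X3D_HEAD_HIDDEN = 2048
SE_RATIO = 1.0 / 16.0


def _se_width(dim_inner: int) -> int:
    """Round the squeeze-excitation width to a multiple of 8, minimum 8."""
    return max(8, int(dim_inner * SE_RATIO + 4) // 8 * 8)


def _stem(in_channels: int = 3) -> nn.Sequential:
    c = X3D_STEM_CHANNELS
    return nn.Sequential(
        nn.Conv(in_channels, c, (1, 3, 3), stride=(1, 2, 2), padding=(0, 1, 1)),
        nn.Conv(c, c, (5, 1, 1), stride=1, padding=(2, 0, 0), groups=c),
        nn.BatchNorm(c),
        nn.ReLU(),
    )


def _bottleneck_block(dim_in: int, dim_out: int, dim_inner: int,
                      spatial_stride: int, use_se: bool) -> nn.ResBlock:
    main = [
        nn.Conv(dim_in, dim_inner, 1),
        nn.BatchNorm(dim_inner),
        nn.ReLU(),
        nn.Conv(dim_inner, dim_inner, 3, stride=(1, spatial_stride, spatial_stride),
                padding=1, groups=dim_inner),
        nn.BatchNorm(dim_inner),
    ]
    if use_se:
        main.append(nn.SqueezeExcite(dim_inner, _se_width(dim_inner)))
    main += [
        nn.Swish(),
        nn.Conv(dim_inner, dim_out, 1),
        nn.BatchNorm(dim_out),
    ]
    shortcut = None
    if dim_in != dim_out or spatial_stride != 1:
        shortcut = nn.Sequential(
            nn.Conv(dim_in, dim_out, 1, stride=(1, spatial_stride, spatial_stride)),
            nn.BatchNorm(dim_out),
        )
    return nn.ResBlock(nn.Sequential(*main), shortcut)


def build_x3d_m_trunk(in_channels: int = 3) -> nn.Sequential:
    """Stem plus the four residual stages (the five convolutional blocks)."""
    layers: list[nn.Module] = [_stem(in_channels)]
    dim_in = X3D_STEM_CHANNELS
    for depth, dim_out, dim_inner in X3D_M_STAGES:
        blocks = []
        for idx in range(depth):
            blocks.append(_bottleneck_block(
                dim_in, dim_out, dim_inner,
                spatial_stride=2 if idx == 0 else 1,
                use_se=(idx % 2 == 0)))
            dim_in = dim_out
        layers.append(nn.Sequential(*blocks))
    return nn.Sequential(*layers)


class X3DHead(nn.Module):
    """Projection head: conv 192->432, pool, 432->2048->classes."""

    def __init__(self, num_classes: int):
        super().__init__()
        self.conv5 = nn.Conv(X3D_EMBED_CHANNELS, X3D_HEAD_INNER, 1)
        self.bn5 = nn.BatchNorm(X3D_HEAD_INNER)
        self.relu5 = nn.ReLU()
        self.pool = nn.GlobalAvgPool()
        self.fc1 = nn.Linear(X3D_HEAD_INNER, X3D_HEAD_HIDDEN, bias=True)
        self.relu6 = nn.ReLU()
        self.proj = nn.Linear(X3D_HEAD_HIDDEN, num_classes, bias=True)

    def forward(self, x):
        x = self.relu5(self.bn5(self.conv5(x)))
        x = self.pool(x)
        return self.proj(self.relu6(self.fc1(x)))

    def backward(self, grad):
        grad = self.fc1.backward(self.relu6.backward(self.proj.backward(grad)))
        grad = self.pool.backward(grad)
        return self.conv5.backward(self.bn5.backward(self.relu5.backward(grad)))


class X3DClassifier(nn.Module):
    def __init__(self, num_classes: int = 400, in_channels: int = 3):
        super().__init__()
        self.trunk = build_x3d_m_trunk(in_channels)
        self.head = X3DHead(num_classes)

    def forward(self, x):
        return self.head(self.trunk(x))

    def backward(self, grad):
        return self.trunk.backward(self.head.backward(grad))


def x3d_m_embedding_shape(clip_length: int, side: int) -> tuple[int, int, int, int]:
    if side % 32:
        raise ConfigurationError(
            f"spatial side {side} not divisible by the 32x stride of X3D-M")
    return (X3D_EMBED_CHANNELS, clip_length, side // 32, side // 32)
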