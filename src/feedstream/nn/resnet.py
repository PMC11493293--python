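"""Residual convolutional backbone for the two image streams.

The full profile is the canonical 50-layer residual network: a 7×7 stride-2
stem convolution with max pooling, four stages of bottleneck units
(1×1 → 3×3 → 1×1 convolutions with an identity or 1×1-projection shortcut
added across the unit), global average pooling and a fully connected
classifier. With stage block counts (3, 4, 6, 3) the main path has
1 + 3×(3+4+6+3) = 49 convolution layers (50 weighted layers with the
classifier), and a 224×224×3 input reaches the pooling layer as a
7×7×2048 feature map.

A ``reduced`` profile (block counts (1, 1, 1, 1), ``base_width`` 8, 64×64
input) trains in minutes on one CPU while keeping the same topology; the
layer-count and output-shape formulas are width-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm,
    Conv2d,
    Dense,
    GlobalAvgPool2d,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = ["ResidualBackboneConfig", "ResidualBlock", "build_residual_backbone", "REDUCED_CONFIG"]


class NetworkError(ValueError):
    """Raised for invalid network configurations."""


@dataclass(frozen=True)
class ResidualBackboneConfig:
    """Structure of the residual backbone.

    ``base_width`` is the stem's channel count; stage s uses
    ``base_width·2^s`` mid-channels, expanded ×4 on the block output when
    ``bottleneck`` is true. The canonical network is ``base_width=64`` with
    blocks (3, 4, 6, 3).
    """

    stage_block_counts: tuple[int, int, int, int] = (3, 4, 6, 3)
    input_size: tuple[int, int, int] = (224, 224, 3)
    n_classes: int = 3
    bottleneck: bool = True
    base_width: int = 64

    def __post_init__(self) -> None:
        if len(self.stage_block_counts) != 4 or any(b < 1 for b in self.stage_block_counts):
            raise NetworkError(
                f"stage_block_counts must be 4 integers >= 1, got {self.stage_block_counts}"
            )
        if self.n_classes < 2:
            raise NetworkError(f"n_classes must be >= 2, got {self.n_classes}")
        h, w, c = self.input_size
        if h < 32 or w < 32 or c < 1:
            raise NetworkError(f"input_size must be >= 32x32 with >= 1 channel, got {self.input_size}")
        if self.base_width < 1:
            raise NetworkError("base_width must be >= 1")


REDUCED_CONFIG = ResidualBackboneConfig(
    stage_block_counts=(1, 1, 1, 1), input_size=(64, 64, 3), base_width=8
)


class ResidualBlock(Layer):
    """One residual unit: main convolution path plus a cross-layer shortcut.

    Bottleneck form: 1×1 (reduce) → 3×3 → 1×1 (expand ×4); basic form: two
    3×3 convolutions. The shortcut is the identity when shapes match, else
    a 1×1 projection convolution with batch norm. The unit output is
    ReLU(main + shortcut).
    """

    def __init__(
        self,
        in_ch: int,
        mid_ch: int,
        stride: int,
        bottleneck: bool,
        rng: np.random.Generator,
    ) -> None:
        out_ch = mid_ch * 4 if bottleneck else mid_ch
        if bottleneck:
            convs = [
                Conv2d(in_ch, mid_ch, 1, rng=rng, bias=False),
                BatchNorm(mid_ch),
                ReLU(),
                Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, rng=rng, bias=False),
                BatchNorm(mid_ch),
                ReLU(),
                Conv2d(mid_ch, out_ch, 1, rng=rng, bias=False),
                BatchNorm(out_ch),
            ]
        else:
            convs = [
                Conv2d(in_ch, mid_ch, 3, stride=stride, pad=1, rng=rng, bias=False),
                BatchNorm(mid_ch),
                ReLU(),
                Conv2d(mid_ch, out_ch, 3, pad=1, rng=rng, bias=False),
                BatchNorm(out_ch),
            ]
        self.main = Sequential(convs)
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Sequential | None = Sequential(
                [Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng, bias=False), BatchNorm(out_ch)]
            )
        else:
            self.shortcut = None
        self.out_ch = out_ch
        self.n_main_convs = 3 if bottleneck else 2
        self._mask = None

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.main.forward(x, train=train)
        short = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        pre = main + short
        if train:
            self._mask = pre > 0
        return np.maximum(pre, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dpre = dout * self._mask
        self._mask = None
        dx = self.main.backward(dpre)
        if self.shortcut is None:
            dx = dx + dpre
        else:
            dx = dx + self.shortcut.backward(dpre)
        return dx


def build_residual_backbone(
    config: ResidualBackboneConfig = ResidualBackboneConfig(),
    seed: int = 0,
) -> tuple[Sequential, dict]:
    """Build the backbone and report its structural summary.

    Returns
    -------
    model : Sequential
        Layers: stem conv/BN/ReLU/max-pool, four residual stages, global
        average pooling, fully connected classifier (logits output).
    summary : dict
        ``conv_layers`` — main-path convolution count (stem + per-block
        convolutions; projection shortcuts excluded by convention);
        ``weighted_layers`` — conv_layers plus the classifier;
        ``prepool_shape`` — (H, W, C) entering the pooling layer;
        ``stage_channels`` — output channels per stage.
    """
    rng = np.random.default_rng(seed)
    h, w, c_in = config.input_size
    width = config.base_width

    layers: list[Layer] = [
        Conv2d(c_in, width, 7, stride=2, pad=3, rng=rng, bias=False),
        BatchNorm(width),
        ReLU(),
        MaxPool2d(),
    ]
    h_out, w_out = h // 2 // 2, w // 2 // 2

    in_ch = width
    stage_channels = []
    for s, n_blocks in enumerate(config.stage_block_counts):
        mid = width * (2**s)
        for b in range(n_blocks):
            stride = 2 if (s > 0 and b == 0) else 1
            block = ResidualBlock(in_ch, mid, stride, config.bottleneck, rng)
            layers.append(block)
            in_ch = block.out_ch
            if stride == 2:
                h_out, w_out = h_out // 2, w_out // 2
        stage_channels.append(in_ch)

    layers.append(GlobalAvgPool2d())
    layers.append(Dense(in_ch, config.n_classes, rng=rng))
    model = Sequential(layers)

    convs_per_block = 3 if config.bottleneck else 2
    n_convs = 1 + convs_per_block * sum(config.stage_block_counts)
    summary = {
        "conv_layers": n_convs,
        "weighted_layers": n_convs + 1,
        "prepool_shape": (h_out, w_out, in_ch),
        "stage_channels": stage_channels,
        "n_classes": config.n_classes,
        "input_size": list(config.input_size),
        "stage_block_counts": list(config.stage_block_counts),
        "bottleneck": config.bottleneck,
        "base_width": config.base_width,
    }
    return model, summary
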