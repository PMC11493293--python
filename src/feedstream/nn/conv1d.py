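"""1-D convolutional classifier for the GLCM descriptor stream.

The texture descriptor is a short ordered vector (16 values at the default
configuration), so its classifier convolves along the width only: stacked
conv/batch-norm/ReLU/pool blocks, a flatten, one hidden dense layer and a
3-way output. Defaults (two blocks of 32 and 64 filters, kernel 3, pool 2,
dense 64) train in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm,
    Conv1d,
    Dense,
    Flatten,
    MaxPool1d,
    ReLU,
    Sequential,
)
from .resnet import NetworkError

__all__ = ["Conv1dNetConfig", "build_conv1d_net"]


@dataclass(frozen=True)
class Conv1dNetConfig:
    """Structure of the 1-D network: (filters, kernel_width, pool_width) blocks."""

    input_length: int = 16
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 3, 2), (64, 3, 2))
    dense_units: int = 64
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.input_length < 2:
            raise NetworkError(f"input_length must be >= 2, got {self.input_length}")
        if not self.conv_blocks:
            raise NetworkError("at least one conv block is required")
        if self.n_classes < 2:
            raise NetworkError(f"n_classes must be >= 2, got {self.n_classes}")
        for blk in self.conv_blocks:
            if len(blk) != 3 or any(v < 1 for v in blk):
                raise NetworkError(f"conv block must be (filters, kernel, pool) >= 1, got {blk}")


def build_conv1d_net(config: Conv1dNetConfig = Conv1dNetConfig(), seed: int = 0) -> Sequential:
    """Build the 1-D convolutional classifier (logits output).

    Input layout is (N, 1, input_length). Convolutions use 'same' zero
    padding (kernel//2); each pool halves the length, which must stay even
    and positive — a kernel or pool wider than the remaining length raises
    :class:`NetworkError`.
    """
    rng = np.random.default_rng(seed)
    layers = []
    in_ch, length = 1, config.input_length
    for filters, kernel, pool in config.conv_blocks:
        if kernel > length + 2 * (kernel // 2):
            raise NetworkError(f"kernel {kernel} wider than remaining length {length}")
        layers += [
            Conv1d(in_ch, filters, kernel, pad=kernel // 2, rng=rng),
            BatchNorm(filters),
            ReLU(),
        ]
        length = length + 2 * (kernel // 2) - kernel + 1
        if pool > 1:
            if pool != 2:
                raise NetworkError("only pool width 2 is supported")
            if length % 2 or length < 2:
                raise NetworkError(f"cannot pool length {length} by 2")
            layers.append(MaxPool1d())
            length //= 2
        in_ch = filters
    layers += [
        Flatten(),
        Dense(in_ch * length, config.dense_units, rng=rng),
        ReLU(),
        Dense(config.dense_units, config.n_classes, rng=rng),
    ]
    return Sequential(layers)
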