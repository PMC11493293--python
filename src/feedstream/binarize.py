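"""Binarization of frames for the spatial stream.

Bright specular splash regions on the water surface are the spatial cue for
feeding intensity: the splashier the surface, the larger the white area of
the binary image. Two thresholding rules are provided:

* ``dual_threshold`` (default): a pixel is foreground when its saturation is
  low and its value is high in HSV space — ``S < T_S and V > T_V`` — which
  isolates bright, unsaturated (white) reflections;
* ``mean_gray``: a pixel is foreground when its gray level is >= the image's
  mean gray level (ties map to foreground).

Foreground is stored as 255 (not 1) so binary images round-trip through
ordinary image files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .flow import to_grayscale

__all__ = ["BinarizationConfig", "BinarizeError", "binarize", "foreground_fraction"]


class BinarizeError(ValueError):
    """Raised for empty or non-binary inputs and invalid thresholds."""


@dataclass(frozen=True)
class BinarizationConfig:
    """Thresholding rule and its parameters (0–255 scale).

    ``T_S``/``T_V`` apply in ``dual_threshold`` mode: saturation strictly
    below ``T_S`` and value strictly above ``T_V`` marks foreground.
    """

    mode: str = "dual_threshold"
    T_S: float = 60.0
    T_V: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("mean_gray", "dual_threshold"):
            raise BinarizeError(f"unknown binarization mode {self.mode!r}")
        if not (0 <= self.T_S <= 255 and 0 <= self.T_V <= 255):
            raise BinarizeError(f"thresholds must lie in [0, 255], got T_S={self.T_S}, T_V={self.T_V}")


def binarize(image: np.ndarray, config: BinarizationConfig = BinarizationConfig()) -> np.ndarray:
    """Map an 8-bit image to a {0, 255} binary image under ``config``.

    ``mean_gray`` compares the gray level (Rec. 601 luma for RGB input)
    against the image mean with >= ties to foreground; ``dual_threshold``
    applies the strict saturation/value rule on the HSV representation.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise BinarizeError("empty image")
    if config.mode == "mean_gray":
        gray = to_grayscale(image)
        mask = gray >= gray.mean()
    else:
        if image.ndim == 2:
            image = np.repeat(image[:, :, None], 3, axis=2)
        hsv = rgb2hsv(image[:, :, :3])
        sat = hsv[..., 1] * 255.0
        val = hsv[..., 2] * 255.0
        mask = (sat < config.T_S) & (val > config.T_V)
    return np.where(mask, 255, 0).astype(np.uint8)


def foreground_fraction(binary: np.ndarray) -> float:
    """Fraction of foreground (255) pixels of a binary image, in [0, 1]."""
    binary = np.asarray(binary)
    if binary.size == 0:
        raise BinarizeError("empty image")
    values = np.unique(binary)
    if not np.isin(values, (0, 255)).all():
        raise BinarizeError(f"input is not binary; found values {values[:10]}")
    return float((binary == 255).mean())
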