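"""Class activation maps for the 2-D stream classifiers.

A backbone ending in global average pooling followed by a linear classifier
admits the classic class-activation-map construction: the classifier weight
vector of a target class, applied channel-wise to the final convolutional
feature maps, gives a spatial map of that class's evidence. The positive
part is bilinearly upsampled to the input size and min–max normalized;
overlays blend a blue→red colormap onto the input (deeper red = more model
attention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v2 as imageio
import numpy as np
from skimage.transform import resize

from .dataio import LABELS
from .nn.layers import Dense, GlobalAvgPool2d, Sequential

__all__ = ["CamError", "ActivationMap", "class_activation_map", "save_overlays"]


class CamError(ValueError):
    """Raised when a model has no global-pooling classifier head."""


@dataclass
class ActivationMap:
    """Normalized heatmap in [0, 1] with its overlay on the input frame."""

    heatmap: np.ndarray
    target_class: str
    overlay: np.ndarray


def _split_head(model: Sequential) -> tuple[Sequential, Dense]:
    layers = model.layers
    gap_idx = [i for i, l in enumerate(layers) if isinstance(l, GlobalAvgPool2d)]
    if not gap_idx:
        raise CamError("model has no global-average-pooling classifier head")
    idx = gap_idx[-1]
    tail = [l for l in layers[idx + 1 :] if isinstance(l, Dense)]
    if len(tail) != 1 or not isinstance(layers[idx + 1], Dense):
        raise CamError("expected a single dense classifier directly after global pooling")
    return Sequential(layers[:idx]), layers[idx + 1]


def _blue_red(x: np.ndarray) -> np.ndarray:
    """Simple blue→red colormap on [0, 1] (through green mid-tones)."""
    r = np.clip(2 * x - 0.5, 0, 1)
    g = 1.0 - np.abs(2 * x - 1.0)
    b = np.clip(1.5 - 2 * x, 0, 1)
    return np.stack([r, g, b], axis=-1)


def class_activation_map(
    model: Sequential,
    image: np.ndarray,
    target_class: Union[str, int],
    raw: bool = False,
) -> ActivationMap:
    """Compute the activation map of ``target_class`` for one input image.

    Parameters
    ----------
    model : Sequential
        A 2-D stream classifier ending in global average pooling + dense.
    image : np.ndarray
        One input sample, either NCHW-style (C, H, W) floats as fed to the
        model, or an (H, W, 3) uint8 frame (converted automatically).
    target_class : str or int
        Class name (none/weak/strong) or index.
    raw : bool
        If true, skip min–max normalization of the heatmap.

    Returns
    -------
    ActivationMap
        ``heatmap`` of the input's spatial size in [0, 1] (a constant map
        normalizes to all zeros) and an RGB ``overlay``.
    """
    if isinstance(target_class, str):
        if target_class not in LABELS:
            raise CamError(f"unknown class {target_class!r}; expected one of {LABELS}")
        class_idx = LABELS.index(target_class)
        class_name = target_class
    else:
        class_idx = int(target_class)
        if not 0 <= class_idx < len(LABELS):
            raise CamError(f"class index {class_idx} out of range")
        class_name = LABELS[class_idx]

    image = np.asarray(image)
    if image.ndim == 3 and image.shape[-1] == 3 and image.dtype == np.uint8:
        x = image.astype(np.float64).transpose(2, 0, 1) / 255.0
        display = image
    elif image.ndim == 3:
        x = image.astype(np.float64)
        display = np.clip(x.transpose(1, 2, 0) * 255, 0, 255).astype(np.uint8)
    else:
        raise CamError(f"expected a single (C, H, W) or (H, W, 3) image, got shape {image.shape}")

    features, classifier = _split_head(model)
    fmaps = features.forward(x[None], train=False)[0]  # (C, h, w)
    weights = classifier.W.value[:, class_idx]  # (C,)
    cam = np.maximum(np.tensordot(weights, fmaps, axes=(0, 0)), 0.0)

    h, w = x.shape[1], x.shape[2]
    cam = resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False)
    if not raw:
        span = cam.max() - cam.min()
        cam = (cam - cam.min()) / span if span > 0 else np.zeros_like(cam)

    colored = (_blue_red(np.clip(cam, 0, 1)) * 255).astype(np.uint8)
    overlay = (0.5 * display + 0.5 * colored).round().astype(np.uint8)
    return ActivationMap(heatmap=cam, target_class=class_name, overlay=overlay)


def save_overlays(maps: list[ActivationMap], out_dir) -> Path:
    """Write CAM overlays as zero-padded PNGs into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(maps):
        imageio.imwrite(out_dir / f"cam_{i:05d}.png", m.overlay)
    return out_dir
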