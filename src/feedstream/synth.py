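"""Synthetic feeding-scene generator.

Renders labeled clips that realize the three feeding-intensity classes as
they appear from an overhead camera in a rearing tank:

* ``none``   — calm water: static fish silhouettes, sensor noise only;
* ``weak``   — localized response: slow fish movement, occasional small
  specular splash highlights;
* ``strong`` — vigorous feeding: fast coherent fish motion and frequent,
  large splash highlights.

Fish are dark ellipses advected by a seeded random walk; splashes are bright
(near-saturated) disks with a short lifetime, because the spatial stream
keys on bright reflective splash regions. Rendering is grayscale internally
and replicated to three channels on export so RGB-consuming stages run
unchanged. Everything is driven by one integer seed: an identical
:class:`SceneConfig` yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v2 as imageio
import numpy as np
from skimage.draw import disk, ellipse

from .dataio import LABELS, FrameSequence


class SynthError(ValueError):
    """Raised for invalid scene configurations or unknown class labels."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic feeding scene.

    Defaults mirror the recording conditions the pipeline targets: 480×270 px
    clips at 24 fps of roughly seven seconds (168 frames). ``motion_scale``
    is the mean per-frame step length of a fish in pixels; ``splash_rate``
    is the expected number of new specular splash disks per frame.
    """

    frame_size: tuple[int, int] = (270, 480)  # (height, width)
    n_frames: int = 168
    fps: float = 24.0
    n_fish: int = 12
    motion_scale: float = 0.0
    splash_rate: float = 0.0
    splash_radius: float = 4.0
    surface_noise_sigma: float = 3.0
    background_level: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if h < 32 or w < 32:
            raise SynthError(f"frame_size components must be >= 32, got {self.frame_size}")
        if self.n_frames < 2:
            raise SynthError(f"n_frames must be >= 2, got {self.n_frames}")
        for name in ("motion_scale", "splash_rate", "splash_radius", "surface_noise_sigma"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if not (0 <= self.background_level <= 255):
            raise SynthError("background_level must be in [0, 255]")
        if self.n_fish < 0:
            raise SynthError("n_fish must be >= 0")
        if self.fps <= 0:
            raise SynthError("fps must be positive")


@dataclass
class LabeledSequence:
    """A rendered clip together with its class label and generating config."""

    frames: FrameSequence
    label: str
    config_used: SceneConfig

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise SynthError(f"label must be one of {LABELS}, got {self.label!r}")


# Class presets: motion_scale, splash_rate and splash_radius are strictly
# ordered none < weak < strong; 'none' has zero motion and zero splashes
# (calm water). Magnitudes are free parameters chosen so that inter-frame
# motion energy, bright-pixel area and texture complexity separate the
# classes at any frame size >= 64 px.
_PRESETS = {
    "none": dict(motion_scale=0.0, splash_rate=0.0, splash_radius=2.0),
    "weak": dict(motion_scale=1.5, splash_rate=2.0, splash_radius=3.5),
    "strong": dict(motion_scale=5.0, splash_rate=6.0, splash_radius=7.0),
}


def class_preset(label: str, **overrides) -> SceneConfig:
    """Return the scene configuration realizing one feeding-intensity class.

    Keyword overrides (e.g. ``frame_size``, ``n_frames``, ``seed``) adjust
    scale without touching the class-defining motion/splash parameters
    unless explicitly given.
    """
    if label not in _PRESETS:
        raise SynthError(f"unknown feeding-intensity label {label!r}; expected one of {LABELS}")
    params = dict(_PRESETS[label])
    params.update(overrides)
    return SceneConfig(**params)


def _fish_axes(frame_size: tuple[int, int]) -> tuple[int, int]:
    h, w = frame_size
    scale = min(h, w)
    return max(2, scale // 16), max(1, scale // 36)


def generate_sequence(config: SceneConfig, label: str = "none") -> LabeledSequence:
    """Render one clip from a scene configuration.

    Fish are dark ellipses oriented along their heading and advected by a
    random walk with mean step ``motion_scale``; new splash disks arrive per
    frame with Poisson(``splash_rate``) counts, live >= 2 frames at
    near-saturated intensity, then vanish. i.i.d. Gaussian noise with
    ``surface_noise_sigma`` is added and the result clipped to [0, 255].
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_size
    ax_a, ax_b = _fish_axes(config.frame_size)

    pos = rng.uniform([0, 0], [h, w], size=(config.n_fish, 2))
    heading = rng.uniform(0, 2 * np.pi, size=config.n_fish)

    splashes: list[list] = []  # [row, col, radius, frames_left]
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    for t in range(config.n_frames):
        img = np.full((h, w), float(config.background_level))

        if config.motion_scale > 0 and t > 0:
            heading += rng.normal(0.0, 0.5, size=config.n_fish)
            step = rng.gamma(4.0, config.motion_scale / 4.0, size=config.n_fish)
            pos[:, 0] += step * np.sin(heading)
            pos[:, 1] += step * np.cos(heading)
            pos[:, 0] %= h
            pos[:, 1] %= w

        for (r, c), th in zip(pos, heading):
            rr, cc = ellipse(r, c, ax_a, ax_b, shape=(h, w), rotation=float(th))
            img[rr, cc] = 40.0  # dark fish body

        if config.splash_rate > 0:
            for _ in range(rng.poisson(config.splash_rate)):
                radius = config.splash_radius * rng.uniform(0.6, 1.3)
                splashes.append(
                    [rng.uniform(0, h), rng.uniform(0, w), max(radius, 1.0), 2 + rng.poisson(1.0)]
                )
        for s in splashes:
            rr, cc = disk((s[0], s[1]), s[2], shape=(h, w))
            img[rr, cc] = 255.0  # specular highlight
            s[3] -= 1
        splashes = [s for s in splashes if s[3] > 0]

        if config.surface_noise_sigma > 0:
            img += rng.normal(0.0, config.surface_noise_sigma, size=(h, w))
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    rgb = np.repeat(frames[..., None], 3, axis=3)
    seq = FrameSequence(frames=rgb, fps=config.fps, source_id=f"synth-{config.seed}", label=label)
    return LabeledSequence(frames=seq, label=label, config_used=config)


def _sequence_seed(master_seed: int, class_index: int, replicate: int) -> int:
    """Deterministic, order-independent per-sequence seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), class_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    **preset_overrides,
) -> list[LabeledSequence]:
    """Generate a balanced labeled dataset of ``3 × n_per_class`` clips.

    Per-sequence seeds are derived from ``seed`` by fixed integer hashing of
    (seed, class index, replicate), so any subset of the dataset is
    reproducible independently of generation order.
    """
    if n_per_class < 1:
        raise SynthError(f"n_per_class must be >= 1, got {n_per_class}")
    dataset = []
    for ci, label in enumerate(LABELS):
        for rep in range(n_per_class):
            cfg = class_preset(label, seed=_sequence_seed(seed, ci, rep), **preset_overrides)
            ls = generate_sequence(cfg, label=label)
            ls.frames.source_id = f"{label}-{rep:03d}"
            dataset.append(ls)
    return dataset


def save_sequence(seq: LabeledSequence, out_dir) -> Path:
    """Write a clip as zero-padded PNG frames plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames.frames):
        imageio.imwrite(out_dir / f"frame_{i:05d}.png", frame)
    sidecar = {
        "label": seq.label,
        "fps": seq.frames.fps,
        "config": asdict(seq.config_used),
    }
    (out_dir / "sequence.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def export_mp4(seq: LabeledSequence, out_path) -> Path:
    """Export a clip as MP4; raises SynthError if no video backend exists."""
    out_path = Path(out_path)
    try:
        writer = imageio.get_writer(str(out_path), fps=seq.frames.fps)
    except Exception as exc:
        raise SynthError(
            f"cannot write video {out_path} (is an ffmpeg backend installed?): {exc}"
        ) from exc
    with writer:
        for frame in seq.frames.frames:
            writer.append_data(frame)
    return out_path
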