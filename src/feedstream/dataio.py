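"""Reading frame sequences and stratified dataset splitting.

Clips are the unit of classification: a clip is an ordered stack of RGB
frames with an optional feeding-intensity label (``none``/``weak``/``strong``).
Clips live on disk as directories of zero-padded PNG/JPEG frames with a JSON
sidecar, or as video files where a decoding backend is available.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import imageio.v2 as imageio
import numpy as np
import pandas as pd

LABELS = ("none", "weak", "strong")

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_EXTS = {".mp4", ".avi", ".mov", ".mkv"}


class DataIOError(ValueError):
    """Raised for unreadable inputs, mixed frame sizes or bad split specs."""


@dataclass
class FrameSequence:
    """An ordered stack of H×W×3 uint8 frames sampled at a fixed rate.

    Attributes
    ----------
    frames : np.ndarray
        Array of shape (n_frames, H, W, 3), dtype uint8.
    fps : float
        Frame rate in frames per second.
    source_id : str
        Identifier of the originating clip (directory or file stem).
    label : str or None
        Feeding-intensity label, one of ``none``/``weak``/``strong``.
    """

    frames: np.ndarray
    fps: float = 24.0
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise DataIOError(
                f"frames must have shape (n, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise DataIOError("a FrameSequence needs at least one frame")
        if self.frames.dtype != np.uint8:
            lo, hi = self.frames.min(), self.frames.max()
            if lo < 0 or hi > 255:
                raise DataIOError(f"pixel values outside [0, 255]: [{lo}, {hi}]")
            self.frames = self.frames.astype(np.uint8)
        if self.label is not None and self.label not in LABELS:
            raise DataIOError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.fps <= 0:
            raise DataIOError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_size(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class SplitSpec:
    """Train/test/validation proportions and the splitting policy.

    ``unit='sequence'`` (default) assigns whole clips to partitions so that no
    frame of a clip leaks into another partition; ``unit='frame'`` splits at
    the frame level.
    """

    train_frac: float = 0.7
    test_frac: float = 0.2
    val_frac: float = 0.1
    seed: int = 0
    unit: str = "sequence"

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.test_frac, self.val_frac)
        if any(f <= 0 for f in fracs):
            raise DataIOError(f"all fractions must be > 0, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise DataIOError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.unit not in ("sequence", "frame"):
            raise DataIOError(f"unit must be 'sequence' or 'frame', got {self.unit!r}")


def _frame_sort_key(path: Path) -> tuple:
    """Zero-padded numeric ordering with lexical tie-break."""
    m = re.search(r"(\d+)", path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def _read_sidecar_label(path: Path) -> Optional[str]:
    for candidate in (path / "sequence.json", path.with_suffix(".json")):
        if candidate.is_file():
            try:
                meta = json.loads(candidate.read_text())
            except json.JSONDecodeError as exc:
                raise DataIOError(f"unreadable sidecar {candidate}: {exc}") from exc
            label = meta.get("label")
            if label is not None:
                return str(label)
    # filename convention: a label token in the directory/file name
    tokens = re.split(r"[^a-z]+", path.stem.lower())
    for lab in LABELS:
        if lab in tokens:
            return lab
    return None


def _to_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.repeat(frame[:, :, None], 3, axis=2)
    if frame.ndim == 3 and frame.shape[2] >= 3:
        return frame[:, :, :3]
    raise DataIOError(f"cannot interpret frame of shape {frame.shape}")


def load_sequence(path, fps: float = 24.0, label: Optional[str] = None) -> FrameSequence:
    """Load a clip from a frame directory or a video file.

    Frames in a directory are ordered by their zero-padded numeric index
    (lexical tie-break). A JSON sidecar (``sequence.json`` inside the
    directory, or ``<dir>.json`` next to it) with a ``label`` key populates
    the label; failing that, a label token in the directory name is used.

    Raises
    ------
    DataIOError
        If the path is missing or empty, frame sizes are mixed, or the video
        cannot be decoded (e.g. no ffmpeg backend is installed).
    """
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"no such file or directory: {path}")

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
            key=_frame_sort_key,
        )
        if not files:
            raise DataIOError(f"no image frames found in directory {path}")
        frames = [_to_rgb(np.asarray(imageio.imread(f))) for f in files]
    elif path.suffix.lower() in _VIDEO_EXTS:
        try:
            reader = imageio.get_reader(str(path))
            frames = [_to_rgb(np.asarray(f)) for f in reader]
            reader.close()
        except Exception as exc:  # imageio raises backend-specific errors
            raise DataIOError(
                f"cannot decode video {path} (is an ffmpeg backend installed?): {exc}"
            ) from exc
        if not frames:
            raise DataIOError(f"video {path} contains no frames")
    else:
        raise DataIOError(f"unsupported input {path}: expected a directory or video")

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DataIOError(f"mixed frame sizes in {path}: {sorted(shapes)}")

    if label is None:
        label = _read_sidecar_label(path)
    return FrameSequence(
        frames=np.stack(frames).astype(np.uint8),
        fps=fps,
        source_id=path.stem if path.is_file() else path.name,
        label=label,
    )


def _largest_remainder(n: int, fracs: Sequence[float]) -> list[int]:
    """Integer quotas for ``n`` items at the given fractions (sum preserved)."""
    exact = [n * f for f in fracs]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = sorted(
        range(len(fracs)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_split(
    items: Sequence,
    spec: SplitSpec,
    label_of: Optional[Callable] = None,
) -> tuple[list, list, list]:
    """Partition labeled items into train/test/validation sets.

    Class proportions are preserved per partition: within each class, the
    per-partition counts are the largest-remainder rounding of
    ``class_count × fraction``, and items are shuffled with ``spec.seed``
    before assignment, so the split is deterministic.

    Parameters
    ----------
    items : sequence
        Labeled units (clips by default). Each must expose a label via
        ``label_of`` (default: the item's ``label`` attribute).
    spec : SplitSpec
        Fractions, seed and splitting unit.
    label_of : callable, optional
        Maps an item to its class label.

    Returns
    -------
    (train, test, val) : three disjoint, exhaustive lists.
    """
    if label_of is None:
        label_of = lambda item: item.label  # noqa: E731
    labels = [label_of(it) for it in items]
    if any(lab is None for lab in labels):
        raise DataIOError("every item must be labeled for a stratified split")
    present = sorted(set(labels), key=lambda l: LABELS.index(l) if l in LABELS else 99)
    for lab in LABELS:
        if lab not in present:
            raise DataIOError(f"class {lab!r} has no items; cannot stratify")

    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_frac, spec.test_frac, spec.val_frac)
    parts: tuple[list, list, list] = ([], [], [])
    for lab in present:
        idx = [i for i, l in enumerate(labels) if l == lab]
        rng.shuffle(idx)
        quotas = _largest_remainder(len(idx), fracs)
        start = 0
        for part, q in zip(parts, quotas):
            part.extend(items[i] for i in idx[start : start + q])
            start += q
    return parts


def split_manifest(
    partitions: tuple[list, list, list],
    label_of: Optional[Callable] = None,
    id_of: Optional[Callable] = None,
) -> pd.DataFrame:
    """Tabulate a split as (source_id, label, partition) rows."""
    if label_of is None:
        label_of = lambda it: it.label  # noqa: E731
    if id_of is None:
        id_of = lambda it: getattr(it, "source_id", str(it))  # noqa: E731
    rows = []
    for name, part in zip(("train", "test", "val"), partitions):
        for it in part:
            rows.append({"source_id": id_of(it), "label": label_of(it), "partition": name})
    return pd.DataFrame(rows, columns=["source_id", "label", "partition"])
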