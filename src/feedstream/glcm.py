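"""Gray-level co-occurrence matrix (GLCM) texture statistics.

The statistical stream describes each frame by how often pairs of quantized
gray levels co-occur at a fixed pixel offset. With the default
configuration — 8 gray levels, offset distance 10 px, the four canonical
directions 0°/45°/90°/135° — each frame yields a 16-value descriptor:
{energy, entropy, contrast, correlation} per direction, ordered
angle-major.

Statistics over a normalized co-occurrence matrix P:

* energy (angular second moment)  ``Asm = ΣΣ P(i,j)²``, in (0, 1], 1 iff
  the matrix has a single nonzero cell (perfectly uniform texture);
* entropy  ``Ent = −ΣΣ P log P`` (0·log 0 := 0), 0 iff a single cell
  carries all mass, maximal for a uniform matrix;
* contrast  ``Con = ΣΣ (i−j)² P``, 0 iff all mass is diagonal;
* correlation  ``Corr = (ΣΣ i·j·P − μx·μy) / (σx·σy)`` with marginal
  means/SDs, defined as 0 when either marginal is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import to_grayscale

__all__ = [
    "GlcmConfig",
    "Glcm",
    "GlcmFeatureVector",
    "GlcmError",
    "quantize_gray",
    "compute_glcm",
    "glcm_statistics",
    "feature_vector",
    "ANGLE_OFFSETS",
]


class GlcmError(ValueError):
    """Raised for invalid configurations or degenerate images."""


# Offset (row, col) per angle, image-row-major coordinates with 45°
# pointing up-right (common GLCM practice).
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

STAT_NAMES = ("energy", "entropy", "contrast", "correlation")


@dataclass(frozen=True)
class GlcmConfig:
    """Quantization and offset configuration of the descriptor."""

    levels: int = 8
    distance: int = 10
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = False
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise GlcmError(f"levels must be >= 2, got {self.levels}")
        if self.distance < 1:
            raise GlcmError(f"distance must be >= 1, got {self.distance}")
        if not self.angles:
            raise GlcmError("angles must be non-empty")
        bad = [a for a in self.angles if a not in ANGLE_OFFSETS]
        if bad:
            raise GlcmError(f"unsupported angles {bad}; choose from {sorted(ANGLE_OFFSETS)}")
        if self.log_base not in (2.0, 2, np.e):
            raise GlcmError("log_base must be 2 or e")


@dataclass
class Glcm:
    """A normalized co-occurrence matrix for one angle."""

    P: np.ndarray
    config_used: GlcmConfig
    angle: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if (self.P < 0).any():
            raise GlcmError("co-occurrence entries must be non-negative")
        total = self.P.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise GlcmError(f"co-occurrence matrix must be normalized, sums to {total}")


@dataclass
class GlcmFeatureVector:
    """Angle-major concatenation of (energy, entropy, contrast, correlation)."""

    values: np.ndarray
    config_used: GlcmConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = 4 * len(self.config_used.angles)
        if self.values.shape != (expected,):
            raise GlcmError(f"expected {expected} values, got shape {self.values.shape}")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def names(self) -> list[str]:
        return [f"{stat}_{angle}" for angle in self.config_used.angles for stat in STAT_NAMES]


def quantize_gray(image: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize an 8-bit gray image to values 0..levels−1.

    Bin assignment is ``floor(gray × levels / 256)``, so 0 maps to level 0
    and 255 to the top level.
    """
    if levels < 2:
        raise GlcmError(f"levels must be >= 2, got {levels}")
    image = np.asarray(image)
    if image.min() < 0 or image.max() > 255:
        raise GlcmError("quantize_gray expects 8-bit input in [0, 255]")
    return (image.astype(np.int64) * levels) // 256


def compute_glcm(qimage: np.ndarray, config: GlcmConfig, angle: int) -> Glcm:
    """Count co-occurrences of quantized levels at the angle's offset.

    The offset (a, b) is ``distance`` times the unit offset of the angle;
    all pixel pairs (x, y), (x+a, y+b) inside the image are counted. In
    symmetric mode the reversed offset's counts are added. Counts are
    normalized to probabilities.
    """
    if angle not in ANGLE_OFFSETS:
        raise GlcmError(f"unsupported angle {angle}")
    q = np.asarray(qimage)
    if q.ndim != 2:
        raise GlcmError(f"quantized image must be 2-D, got shape {q.shape}")
    if q.max() >= config.levels or q.min() < 0:
        raise GlcmError("quantized values must lie in [0, levels)")

    d = config.distance
    da, db = (off * d for off in ANGLE_OFFSETS[angle])
    h, w = q.shape
    # Valid source region so that (x+da, y+db) stays in bounds.
    r0, r1 = max(0, -da), min(h, h - da)
    c0, c1 = max(0, -db), min(w, w - db)
    if r0 >= r1 or c0 >= c1:
        raise GlcmError(
            f"image of shape {q.shape} has no valid pixel pair at distance {d}, angle {angle}"
        )
    src = q[r0:r1, c0:c1].ravel()
    dst = q[r0 + da : r1 + da, c0 + db : c1 + db].ravel()

    P = np.zeros((config.levels, config.levels), dtype=np.float64)
    np.add.at(P, (src, dst), 1.0)
    if config.symmetric:
        P = P + P.T
    P /= P.sum()
    return Glcm(P=P, config_used=config, angle=angle)


def glcm_statistics(glcm: Glcm, log_base: float | None = None) -> tuple[float, float, float, float]:
    """(energy, entropy, contrast, correlation) of a normalized matrix."""
    P = glcm.P
    total = P.sum()
    if abs(total - 1.0) > 1e-9:
        raise GlcmError(f"matrix must be normalized to sum 1, sums to {total}")
    if log_base is None:
        log_base = glcm.config_used.log_base

    asm = float((P**2).sum())

    nz = P[P > 0]
    log = np.log2 if log_base in (2, 2.0) else np.log
    ent = float(-(nz * log(nz)).sum())

    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    con = float(((i - j) ** 2 * P).sum())

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(levels) * px).sum())
    mu_y = float((np.arange(levels) * py).sum())
    var_x = float(((np.arange(levels) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(levels) - mu_y) ** 2 * py).sum())
    denom = np.sqrt(var_x * var_y)
    if denom == 0:
        corr = 0.0
    else:
        corr = float((((i * j) * P).sum() - mu_x * mu_y) / denom)
    return asm, ent, con, corr


def feature_vector(image: np.ndarray, config: GlcmConfig = GlcmConfig()) -> GlcmFeatureVector:
    """Descriptor of one frame: per-angle GLCM statistics, angle-major.

    RGB input is converted to grayscale (Rec. 601 luma) before
    quantization. At the default configuration the vector has 16 entries.
    """
    gray = np.clip(to_grayscale(image), 0, 255)
    q = quantize_gray(gray.astype(np.uint8), config.levels)
    values = []
    for angle in config.angles:
        g = compute_glcm(q, config, angle)
        values.extend(glcm_statistics(g))
    return GlcmFeatureVector(values=np.array(values), config_used=config)
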