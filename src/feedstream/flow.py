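"""Dense optical flow from the brightness-constancy constraint.

A moving point is assumed to keep its intensity between consecutive frames,
which linearizes to the constraint ``Ix·u + Iy·v + It = 0`` per pixel. The
constraint alone is underdetermined (one equation, two unknowns), so the
flow field is regularized with a global quadratic smoothness penalty and
solved iteratively (Horn–Schunck scheme): the minimizer of

    E(u, v) = sum (Ix·u + Iy·v + It)^2 + alpha^2 · sum (|∇u|^2 + |∇v|^2)

is approached by fixed-point sweeps over the Euler–Lagrange equations with
a local-average approximation of the Laplacian. Flow fields are rendered as
HSV color-wheel images (hue = direction, intensity = magnitude) for the
temporal-stream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, map_coordinates
from skimage.color import hsv2rgb

__all__ = [
    "FlowField",
    "GradientTriple",
    "FlowError",
    "to_grayscale",
    "spatiotemporal_gradients",
    "estimate_flow",
    "flow_energy",
    "flow_to_image",
]


class FlowError(ValueError):
    """Raised for mismatched or non-finite inputs to the flow estimator."""


@dataclass
class FlowField:
    """Per-pixel velocity (u along X/columns, v along Y/rows) in px/frame."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise FlowError(f"u and v must be equal-shape 2-D arrays, got {self.u.shape} vs {self.v.shape}")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise FlowError("flow components must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class GradientTriple:
    """Partial derivatives of intensity along X (columns), Y (rows) and T."""

    Ix: np.ndarray
    Iy: np.ndarray
    It: np.ndarray


# Local-average kernel of the classic iterative scheme: the smoothness term
# couples each pixel to a weighted 8-neighborhood mean.
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an RGB frame (pass-through for 2-D input), float64."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] >= 3:
        return frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114
    raise FlowError(f"cannot convert shape {frame.shape} to grayscale")


def spatiotemporal_gradients(frame_a: np.ndarray, frame_b: np.ndarray) -> GradientTriple:
    """Intensity derivatives between two consecutive grayscale frames.

    Spatial derivatives are central differences of the two-frame average
    (one-sided at the borders); the temporal derivative is the plain
    per-pixel difference ``frame_b − frame_a``.
    """
    a = to_grayscale(frame_a)
    b = to_grayscale(frame_b)
    if a.shape != b.shape:
        raise FlowError(f"frame shapes differ: {a.shape} vs {b.shape}")
    mean = 0.5 * (a + b)
    Iy, Ix = np.gradient(mean)
    return GradientTriple(Ix=Ix, Iy=Iy, It=b - a)


def flow_energy(flow: FlowField, grads: GradientTriple, smoothness_weight: float) -> float:
    """Objective value: data-term residual plus weighted smoothness penalty.

    The smoothness term is the neighborhood quadratic form matching the
    solver's averaging kernel (each pixel against its weighted 8-neighbor
    mean differences), so the reported energy is the discrete objective the
    iteration actually descends.
    """
    data = grads.Ix * flow.u + grads.Iy * flow.v + grads.It
    smooth = 0.0
    for comp in (flow.u, flow.v):
        sq_bar = convolve(comp**2, _AVG_KERNEL, mode="nearest")
        bar = convolve(comp, _AVG_KERNEL, mode="nearest")
        smooth += np.sum(sq_bar - 2 * comp * bar + comp**2)
    return float(np.sum(data**2) + smoothness_weight**2 * smooth)


def _solve_increment(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float,
    n_iterations: int,
    energies: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    g = spatiotemporal_gradients(a, b)
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = alpha**2 + g.Ix**2 + g.Iy**2
    for _ in range(n_iterations):
        u_bar = convolve(u, _AVG_KERNEL, mode="nearest")
        v_bar = convolve(v, _AVG_KERNEL, mode="nearest")
        scale = (g.Ix * u_bar + g.Iy * v_bar + g.It) / denom
        u = u_bar - g.Ix * scale
        v = v_bar - g.Iy * scale
        if energies is not None:
            energies.append(flow_energy(FlowField(u=u, v=v), g, alpha))
    return u, v


def _backwarp(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return map_coordinates(img, [yy + v, xx + u], order=1, mode="nearest")


def estimate_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    smoothness_weight: float = 15.0,
    n_iterations: int = 100,
    n_warps: int = 2,
    return_energy: bool = False,
) -> FlowField | tuple[FlowField, list[float]]:
    """Estimate dense flow between two frames by the iterative global scheme.

    The linearized constraint only holds for sub-pixel motion, so after the
    initial solve the estimate is refined incrementally: the second frame is
    warped back by the current field and the residual flow is re-solved and
    accumulated (``n_warps`` passes). Identical frames give the zero field
    at any setting.

    Parameters
    ----------
    smoothness_weight : float
        Regularization strength alpha (intensity units); larger values give
        smoother fields. Must be > 0.
    n_iterations : int
        Fixed-point sweeps per solve; >= 1.
    n_warps : int
        Incremental warp refinements after the initial solve; >= 0.
    return_energy : bool
        Also return the objective value after every sweep of the initial
        solve (the warped refinements minimize residual objectives of their
        own and are not comparable on one scale).
    """
    if smoothness_weight <= 0:
        raise FlowError("smoothness_weight must be > 0")
    if n_iterations < 1:
        raise FlowError("n_iterations must be >= 1")
    if n_warps < 0:
        raise FlowError("n_warps must be >= 0")
    a = to_grayscale(frame_a)
    b = to_grayscale(frame_b)
    if a.shape != b.shape:
        raise FlowError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise FlowError("input frames contain non-finite values")

    energies: list[float] | None = [] if return_energy else None
    u, v = _solve_increment(a, b, smoothness_weight, n_iterations, energies)
    for _ in range(n_warps):
        b_warped = _backwarp(b, u, v)
        du, dv = _solve_increment(a, b_warped, smoothness_weight, n_iterations)
        u, v = u + du, v + dv
    field = FlowField(u=u, v=v)
    if return_energy:
        return field, energies  # type: ignore[return-value]
    return field


def flow_to_image(flow: FlowField, max_magnitude: float | None = None) -> np.ndarray:
    """Render a flow field as an RGB uint8 image on the HSV color wheel.

    Hue encodes the flow angle ``atan2(v, u)`` over the full wheel;
    brightness encodes magnitude scaled by ``max_magnitude`` (``None`` uses
    the per-image maximum, guarded against zero). Zero flow maps to black,
    the constant reference color.
    """
    mag = flow.magnitude
    if max_magnitude is None:
        max_magnitude = float(mag.max())
    scale = max(float(max_magnitude), 1e-8)
    hue = (np.arctan2(flow.v, flow.u) + np.pi) / (2 * np.pi)
    value = np.clip(mag / scale, 0.0, 1.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return (hsv2rgb(hsv) * 255).round().astype(np.uint8)
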