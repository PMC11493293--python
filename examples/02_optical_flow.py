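"""Estimate dense optical flow on a known translation and render it.

The estimator solves the brightness-constancy constraint Ix·u + Iy·v + It = 0
with a global smoothness penalty (iterative scheme plus incremental warp
refinement). On a smooth texture translated by a known shift the recovered
median flow should match the shift to well under half a pixel.
"""

from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from scipy.ndimage import gaussian_filter

from feedstream import estimate_flow, flow_to_image

rng = np.random.default_rng(0)
texture = gaussian_filter(rng.uniform(0, 255, size=(80, 80)), 2.5)
shift = (2, -1)  # (dx, dy) pixels
moved = np.roll(np.roll(texture, shift[1], axis=0), shift[0], axis=1)

field = estimate_flow(texture, moved)
interior = np.s_[10:-10, 10:-10]
epe = np.hypot(field.u[interior] - shift[0], field.v[interior] - shift[1]).mean()
print(f"true shift       : u={shift[0]}, v={shift[1]} px/frame")
print(
    f"recovered median : u={np.median(field.u[interior]):.2f}, "
    f"v={np.median(field.v[interior]):.2f} px/frame"
)
print(f"mean endpoint err: {epe:.3f} px  (flow is accurate if well below 0.5)")

out = Path("example_output")
out.mkdir(exist_ok=True)
imageio.imwrite(out / "flow.png", flow_to_image(field, max_magnitude=4.0))
print(f"\nflow image written to {out / 'flow.png'}: hue encodes direction,")
print("brightness encodes speed; a uniform patch means coherent motion.")
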