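"""Generate one synthetic feeding scene per intensity class and measure the
statistics that separate them.

The generator renders fish as dark ellipses on a gray water surface and
splashes as near-saturated disks; the three class presets differ in fish
speed, splash arrival rate and splash size. Motion energy (mean absolute
inter-frame difference) and bright-pixel area must order none < weak < strong.
"""

import numpy as np

from feedstream import class_preset, generate_sequence

for label in ("none", "weak", "strong"):
    config = class_preset(label, frame_size=(64, 64), n_frames=50, seed=0)
    clip = generate_sequence(config, label=label)
    gray = clip.frames.frames[..., 0].astype(float)
    motion = np.abs(np.diff(gray, axis=0)).mean()
    bright = (gray >= 250).mean()
    print(
        f"{label:>6}: motion_scale={config.motion_scale:>4.1f} px/frame, "
        f"splash_rate={config.splash_rate:>4.1f}/frame | "
        f"inter-frame diff {motion:6.3f} gray levels, bright pixels {bright * 100:5.2f}%"
    )

print(
    "\nBoth statistics increase strictly with feeding intensity: the motion\n"
    "term drives the temporal (optical-flow) stream and the bright splash\n"
    "area drives the spatial (binarization) stream."
)
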