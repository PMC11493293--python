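"""Compute the 16-value GLCM texture descriptor per class.

Each frame is quantized to 8 gray levels; co-occurrences at distance 10 are
counted along 0/45/90/135 degrees, and energy, entropy, contrast and
correlation are read off each matrix. Calm scenes are more uniform (higher
energy, lower entropy) than splash-covered ones.
"""

from feedstream import GlcmConfig, class_preset, feature_vector, generate_sequence

config = GlcmConfig()  # 8 levels, distance 10, four angles
print("per-class descriptor statistics at 0 degrees:\n")
print(f"{'class':>6} {'energy':>8} {'entropy':>8} {'contrast':>9} {'correlation':>12}")
for label in ("none", "weak", "strong"):
    clip = generate_sequence(
        class_preset(label, frame_size=(64, 64), n_frames=3, seed=1), label=label
    )
    fv = feature_vector(clip.frames.frames[-1], config)
    energy, entropy, contrast, corr = fv.values[:4]
    print(f"{label:>6} {energy:8.4f} {entropy:8.3f} {contrast:9.3f} {corr:12.3f}")

print(
    f"\nfull descriptor length: {len(fv)} values "
    "(4 statistics x 4 angles, angle-major order)\n"
    "Splashes add bright co-occurrence cells: energy falls and entropy rises\n"
    "from none to strong, which is what the 1-D conv classifier learns."
)
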