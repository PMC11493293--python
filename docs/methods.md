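# Methods

This note documents the models and procedures implemented in `feedstream`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Overview

A clip is classified into one of three feeding intensities — `none`,
`weak`, `strong` — by three independent streams fused late:

| stream    | representation                         | classifier             |
|-----------|----------------------------------------|------------------------|
| temporal  | rendered optical-flow image per frame pair | residual 2-D backbone |
| spatial   | binary splash image per frame          | residual 2-D backbone  |
| statistical | 16-value GLCM texture descriptor per frame | 1-D conv network   |

Classification is per *item*, where the item for frame *t* (t ≥ 1) of a
clip is the aligned triple (flow image of frames *t−1, t*; binary image of
frame *t*; GLCM vector of frame *t*). Aligning all three streams on frame
pairs gives one score triple per item, which the fusion rule needs. Clip
decisions are a plurality over item decisions.

## Temporal stream: optical flow

**Model.** Brightness constancy — a moving point keeps its intensity
between frames — linearizes to `Ix·u + Iy·v + It = 0` per pixel. One
equation cannot determine two unknowns, so the field minimizes

    E(u, v) = Σ (Ix·u + Iy·v + It)² + α² · S(u, v),

where `S` is a quadratic smoothness penalty. The minimizer is approached
by the classic fixed-point sweeps in which each pixel is pulled toward its
kernel-weighted neighborhood mean and corrected along the image gradient.

**Numerical choices.**

* Gradients: `Ix`, `Iy` are central differences of the two-frame average
  (one-sided at borders); `It = frame_b − frame_a`. RGB input is reduced
  by the Rec. 601 luma (0.299 R + 0.587 G + 0.114 B).
* Defaults `smoothness_weight α = 15`, `n_iterations = 100`. Larger α
  propagates flow further into untextured water; 100 sweeps suffice at the
  64–270 px frame sizes used here.
* **Warp refinement** (`n_warps = 2` by default): the linearized constraint
  only holds for sub-pixel motion and systematically underestimates shifts
  above ~1 px. After the initial solve, frame B is warped back by the
  current field and the residual flow is re-solved and accumulated. Two
  refinements bring the mean endpoint error on ±3 px translations of
  smooth textures below 0.5 px (the tested property). This is incremental
  estimation at a single scale, not a coarse-to-fine pyramid.
* The reported energy uses the neighborhood quadratic form matching the
  solver's averaging kernel, i.e. the discrete objective the sweeps
  actually descend. The simultaneous (Jacobi-type) update is not strictly
  monotone: near convergence on rough textures the energy can tick up by
  ~10⁻⁵ relative. Tests assert per-sweep non-increase within 10⁻⁴
  relative plus strict overall decrease.
* A uniform brightness change between frames violates constancy by
  construction; robustness to it is *not* claimed and not asserted.

**Rendering.** `flow_to_image` maps angle `atan2(v, u)` to hue over the
full wheel and magnitude to brightness, scaled by `max_magnitude`
(per-image max when unset, guarded against zero). Zero flow renders black.
The pipeline fixes `max_magnitude = 8 px/frame` so that brightness encodes
*absolute* speed — with per-image scaling, a calm scene's noise flow would
render as brightly as a strong scene's motion and the class signal would
be lost.

## Spatial stream: binarization

Two thresholding modes are provided because two rules are plausible:

* `dual_threshold` (default): foreground iff `S < T_S` and `V > T_V` on
  the HSV representation, with strict inequalities; defaults `T_S = 60`,
  `T_V = 200` (0–255 scale). This isolates bright, unsaturated pixels —
  specular splash reflections — and is robust to overall scene brightness.
* `mean_gray`: foreground iff gray ≥ mean gray of the frame. Ties map to
  foreground (≥), so a constant frame maps entirely to foreground.

Foreground is stored as 255 rather than 1 so binary images round-trip
through PNG; the {0, 1} alphabet is a relabeling. `mean_gray` is
idempotent on non-constant images; the constant case is the documented
tie-rule exception.

## Statistical stream: GLCM texture

For a frame quantized to `levels` gray bins (`q = ⌊gray·levels/256⌋`,
default 8), the co-occurrence matrix at angle θ counts pairs
(x, y), (x+a, y+b) with offset (a, b) equal to `distance` (default 10)
times the unit offset of θ. Offsets use image row-major coordinates with
45° pointing up-right: 0° → (0, d), 45° → (−d, d), 90° → (−d, 0),
135° → (−d, −d). Counts are one-directional (asymmetric) by default, with
a symmetric mode that adds the reversed offset; matrices are normalized to
probabilities before statistics — energy ≤ 1 and the entropy logarithm
require probabilities, not raw frequencies.

Per angle, four statistics are read off the normalized matrix P:

* energy (angular second moment) `ΣΣ P²` ∈ (0, 1], 1 iff one cell holds
  all mass;
* entropy `−ΣΣ P log₂ P` with `0·log 0 := 0` (bits by default; natural
  log configurable);
* contrast `ΣΣ (i−j)² P`, 0 iff all mass is diagonal;
* correlation `(ΣΣ ij·P − μx·μy)/(σx·σy)` with marginal means and
  standard deviations, defined as 0 when a marginal is degenerate. This is
  the standard product-moment form measuring gray-level similarity along
  rows/columns.

The descriptor concatenates the four statistics angle-major over the four
angles — 16 values at defaults. In the pipeline the descriptors are
z-scored with train-partition moments before entering the classifier (the
raw statistics differ by orders of magnitude in scale).

## Classifiers

All layers (2-D/1-D convolution via im2col, batch normalization, ReLU,
max pooling, global average pooling, dense) and the training loop are
implemented in numpy with manual backpropagation — a deliberately
lightweight CPU implementation; the models here are small enough that BLAS
matrix products dominate and no accelerator framework is needed.

**Residual backbone (both image streams, independent weights).** Stem
7×7/stride-2 convolution + batch norm + ReLU + max pool, four stages of
bottleneck units (1×1 reduce → 3×3 → 1×1 expand ×4, identity or projection
shortcut, ReLU after the cross-layer addition), global average pooling,
dense classifier. The canonical profile — blocks (3, 4, 6, 3), base width
64, 224×224×3 input — has 1 + 3×16 = 49 main-path convolution layers (50
weighted layers with the classifier; projection shortcuts are excluded
from the count by convention) and reaches pooling at 7×7×2048. The
**reduced profile** — blocks (1, 1, 1, 1), base width 8, 64×64 input —
keeps the same topology at 13 convolution layers and 2×2×256, and is what
the test suite and desk-scale pipeline train. Max pooling is 2×2/stride-2,
which preserves the canonical stage sizes at both 224 and 64 inputs.

**1-D network (GLCM stream).** Two conv blocks (32 then 64 filters,
kernel 3 with same-padding, width-2 max pool) over the 16-long vector,
flatten, dense 64, 3-way output. Trains in seconds.

**Training.** Softmax cross-entropy, adaptive-moment updates
(lr 10⁻³, β₁ 0.9, β₂ 0.999), batch size 32, 20 epochs, random (He)
initialization, no augmentation, no pretraining. All configurable. A fixed
seed makes data generation, splitting, initialization and batch order —
and therefore the entire run — bit-reproducible on a fixed threading
configuration.

## Fusion, aggregation, metrics

* **Vote fusion** (default): majority over the three streams' argmax
  labels. A three-way disagreement falls back to the largest summed score
  triple; exact score ties resolve to the earliest class in
  (none, weak, strong) order. `tie_broken` marks non-majority outcomes.
  Pure score-sum fusion is available (`fusion.method: score_sum`); the
  vote with score fallback honors both decision-level and score-level
  readings of late fusion.
* **Clip aggregation**: plurality over item labels, ties broken toward
  the *stronger* class — a policy choice, conservative for feeding
  control (prefer not to under-read feeding demand).
* **Metrics**: per class one-vs-rest TP/FP/FN/TN from the confusion
  matrix; precision, recall and accuracy reported in percent, F1 as a
  fraction in [0, 1]. Macro (unweighted class mean) averaging is the
  default reading for a three-class report; micro averaging is provided
  and satisfies micro-precision = micro-recall = accuracy for single-label
  data. Zero-support classes are excluded from macro averages with a
  warning. Both frame-level and clip-level fused accuracies are reported,
  since a headline accuracy could be read either way.

## Class activation maps

Both 2-D streams end in global average pooling + dense, so the classic CAM
applies directly: the target class's classifier weight vector contracts
the final-stage feature maps into a spatial evidence map; the positive
part is bilinearly upsampled to the input size and min–max normalized
(a constant map normalizes to zeros). Pre-normalization CAM values are
linear in the classifier weights. Overlays blend a blue→red colormap onto
the input; per-frame overlays can be concatenated to a video where an
ffmpeg backend is available.

## Synthetic feeding scenes

**What it emulates.** The generator renders the three intensity regimes as
an overhead camera would coarsely see them: a mid-gray water surface
(background level 150), dark fish silhouettes (ellipses oriented along
their heading, advected by a seeded random walk with mean step
`motion_scale`), and specular splash highlights (near-saturated disks
arriving at Poisson(`splash_rate`) per frame, living ≥ 2 frames), plus
i.i.d. Gaussian sensor noise (σ = 3 gray levels), clipped to [0, 255].
Brightness encodes splash deliberately: the spatial stream keys on bright
reflective regions, so splashes — not fish — must be the bright content.
Rendering is grayscale replicated to RGB, so color-consuming stages run
unchanged.

**Class presets.** `none`: motion 0, splashes 0 (calm water — the class
definition); `weak`: motion 1.5 px/frame, 2.0 splashes/frame of radius
3.5 px; `strong`: motion 5.0 px/frame, 6.0 splashes/frame of radius 7 px.
All three intensity parameters are strictly ordered across classes. The
weak splash rate is set high enough that essentially every weak frame
carries at least one live splash: the weak class is *defined* by visible
surface fluctuation, and a static stream cannot distinguish a weak frame
with no splash from a calm frame. Defaults target the recording geometry
of the intended deployment (270×480 px, 24 fps, ~7 s clips); the desk
profile renders 64×64.

**Determinism.** One integer seed drives everything; identical configs
give bit-identical clips. Dataset-level seeds derive from the master seed
by hashing (seed, class index, replicate), so any subset regenerates
independently of order.

**What it does not emulate — and what passing tests therefore do not
show.** No photorealistic water, caustics, wave propagation or occlusion;
no fish-body articulation or 3-D geometry; noise is i.i.d. rather than
structured (ripple patterns, compression artifacts, lighting drift). The
synthetic classes are separable by construction once splash visibility is
guaranteed, so held-out accuracies here demonstrate that the pipeline is
wired correctly end to end — features carry the class signal, classifiers
learn it, fusion does not destroy it — not that these accuracies transfer
to real farm video.

## Problem sizes

The test suite and the acceptance script run the desk-scale profile: 20
clips per class, 12-frame 64×64 clips, reduced backbone, 20 epochs —
~460 training items per stream, a full run in a few minutes on one CPU.
The worked example in `examples/05_train_and_fuse.py` uses 10 clips per
class, 8 frames, 12 epochs (~30 s). These sizes are the package's chosen
desk-scale study conditions; all of them are configuration, not code.

## Known limitations

* Clip-level splitting is the default because frame-level splitting of
  24 fps video places near-duplicate frames in different partitions and
  inflates scores; frame-level splitting remains available for
  comparability experiments.
* The flow solver is single-scale; motions well beyond ~5 px/frame would
  need more warp refinements or a genuinely multi-scale estimator, which
  is out of scope.
* Video container I/O (MP4/AVI read, MP4 export) requires an ffmpeg
  backend at run time; frame directories are the always-available format.
* Classification is per frame pair; no temporal model beyond the flow
  pair (no recurrent or 3-D convolutional variants).
* Training from random initialization at the reduced scale is sensitive
  to very small sample counts; below ~8 clips per class the 2-D streams
  may not converge within the default epoch budget.
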