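# feedstream

Three-stream discrimination of fish feeding intensity from overhead video.

## The problem

In recirculating-aquaculture tanks, how vigorously a school feeds is the
signal that drives feeding control: underfeeding slows growth, overfeeding
wastes feed and pollutes the water. An overhead camera sees three visually
distinct regimes — calm water with unresponsive fish (**none**), localized
feeding with visible surface fluctuation (**weak**), and free movement
between food with fierce swimming that stirs the surface (**strong**).
`feedstream` classifies short clips into these three intensities for anyone
building automated feeding control or studying feeding behavior, and ships
a synthetic feeding-scene generator so the whole pipeline is testable and
reproducible without proprietary farm video.

## The method

Three independent feature streams, each with its own classifier, fused at
the prediction-score level:

1. **Temporal — optical flow.** Dense motion between consecutive frames
   from the brightness-constancy constraint
   `Ix·u + Iy·v + It = 0`, regularized with a global quadratic smoothness
   penalty `α²(|∇u|² + |∇v|²)` and solved by iterative sweeps with
   incremental warp refinement. Flow fields are rendered on the HSV color
   wheel (hue = direction, brightness = speed) and classified by a
   residual convolutional backbone — bottleneck units `1×1 → 3×3 → 1×1`
   with cross-layer shortcuts; stage blocks (3, 4, 6, 3) give
   1 + 3×(3+4+6+3) = 49 convolution layers and a 7×7×2048 feature map
   before global average pooling for 224×224×3 input.
2. **Spatial — binarization.** Splashes read as bright, unsaturated
   reflections; a pixel is foreground iff `S < T_S and V > T_V` in HSV
   (mean-gray thresholding is available as an alternative mode). The
   binary image goes to a second residual backbone.
3. **Statistical — GLCM texture.** Frames are quantized to 8 gray levels;
   co-occurrence matrices at pixel distance 10 along 0°/45°/90°/135° yield
   energy `ΣΣP²`, entropy `−ΣΣP log P`, contrast `ΣΣ(i−j)²P` and
   correlation `(ΣΣ ij·P − μxμy)/(σxσy)` — a 16-value descriptor
   classified by a 1-D convolutional network.

The fused decision is a majority vote over the three streams' argmax
labels, with the largest summed score breaking three-way disagreements.
Evaluation reports a 3×3 confusion matrix, accuracy, and per-class/macro
precision, recall and F1; datasets are split 70/20/10 into
train/test/validation at clip level with class proportions preserved.

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`python examples/05_train_and_fuse.py`, ~30 s) generates 30 labeled
synthetic clips, extracts the three representations, trains the three
classifiers and prints:

```
clips: 30, held-out items: 42

 temporal stream accuracy:  92.9%
  spatial stream accuracy: 100.0%
     glcm stream accuracy: 100.0%

fused (vote) accuracy : 100.0% frame level
                        100.0% clip level

ablation over stream subsets:
  temporal                   92.9%
  spatial                   100.0%
  glcm                      100.0%
  temporal+spatial          100.0%
  temporal+glcm             100.0%
  spatial+glcm              100.0%
  temporal+spatial+glcm     100.0%
```

Each accuracy is the percentage of held-out samples assigned the correct
feeding intensity; the ablation grid evaluates every non-empty subset of
streams (single streams use their own scores, pairs use summed scores, the
triple uses the vote). `examples/06_cam.py` then renders a class
activation map showing that the spatial model's "strong" evidence sits on
the splash disks (mean activation 0.49 on splashes vs 0.37 on background
in the run above).

A `feedstream` command-line tool wraps the same stages
(`synth`, `split`, `features`, `train`, `evaluate`, `predict`, `cam`,
`run`); see `feedstream --help`.

## Documentation

`docs/methods.md` describes the model, the synthetic-scene generator, all
tunable parameters with their defaults, numerical choices, and known
limitations.
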