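# Methods

## The measurement

The disc-fovea angle (DFA) is the angle between the line joining the
geometric center of the optic disc to the foveal center and the horizontal
line through the disc center. It is the standard fundus-photographic proxy
for ocular torsion: in rotational strabismus the DFA falls outside its
normal range. `dfa-meter` automates the measurement in three stages:

1. **Segmentation.** A three-class encoder-decoder network labels each
   pixel of a color fundus photograph as background, optic disc, or
   *virtual macular area* — a disc of fixed radius centered on the fovea,
   used because the macula has no sharp photographic boundary. The label
   radius is 400 px at the native 2,584 x 1,985 frame and scales linearly
   with frame width for smaller renders.
2. **Center extraction.** For each structure the largest 8-connected
   component of its class is selected and its center taken as the center of
   the minimum enclosing circle (Welzl's algorithm applied to the convex
   hull of the component). An axis-aligned bounding-rectangle center is
   available as an alternative (`method="rectangle"`); for the near-circular
   regions involved the two agree to within a pixel.
3. **Angle.** With disc center (OX, OY) and macular center (MX, MY) in
   image coordinates (y down),

   DFA = arctan(|OY − MY| / |OX − MX|) · 180/π,

   taken as 90° when OX = MX, and negated when MY > OY (fovea below the
   disc center). The output always lies in [−90°, +90°], is invariant to
   translation of both centers, and is antisymmetric under reflection
   across the horizontal through the disc center.

## Segmentation networks

The primary model is DeepLabv3+ with a MobileNetV2 encoder. The encoder is
a stride-2 stem convolution followed by 17 inverted-residual bottlenecks
(expand 1x1 → depthwise 3x3 → project 1x1, residual addition exactly when
stride is 1 and input/output channel counts match), partitioned 1 + 2 + 14:
the low-level feature tap sits after the first three bottlenecks at stride
4, and the remaining 14 produce high-level features at output stride 16
(the last stride-2 stage runs at stride 1 with doubled dilation). ASPP
applies a 1x1 branch, three 3x3 atrous branches at rates (6, 12, 18), and a
global-pooling branch, then projects the concatenation. The decoder
upsamples the ASPP output to the low-level resolution, concatenates the
1x1-projected low-level features, refines with two 3x3 convolutions and
upsamples bilinearly to input resolution with 3 output channels. U-Net
(4 down / 4 up levels, bilinear upsampling) and PSPNet (pyramid bins
1, 2, 3, 6 over a reduced stride-8 backbone) are included as canonical
baselines.

All channel widths scale with a `width_multiplier`, so the same
architecture runs at publication scale (1.0, 512 x 512 inputs) and desk
scale (0.25, 128 x 128 inputs).

The networks run on a small numpy reverse-mode autodiff engine inside the
package (`dfa_meter.nn`): dense/depthwise convolution via im2col strided
views, batch normalization with running statistics, bilinear resizing and
adaptive average pooling expressed as separable linear maps, and softmax
cross-entropy. Every op's gradient is validated against central finite
differences in the test suite. Computation is float32 throughout.

## Training protocol

* Split: 7:3 into training pool and test set, then 9:1 into training and
  validation sets, by seeded uniform shuffle with floor arithmetic — a
  682-image dataset yields 477/205 and 429/48.
* Loss: unweighted per-pixel cross-entropy over the three classes (the
  standard choice for these architectures).
* Optimizer: Adam. Default learning rate 0.00005 and 100 epochs
  (`TrainConfig`), batch size 4; images are normalized per channel to
  [0, 1].
* Model selection: the checkpoint with the lowest validation loss;
  ties go to the earliest epoch.
* No data augmentation and no pretrained weights; training is from
  scratch, seeded and reproducible.
* Ties in the per-pixel argmax at prediction time resolve to the lowest
  class index.

Center extraction and the center errors DO/DM are computed by default at
the native resolution of the input image (the predicted mask is upscaled
nearest-neighbor), because the virtual-macula radius and the reported
center errors are defined in native pixels; a flag switches to
network-resolution evaluation.

## Evaluation metrics

Per class c, with one-vs-rest pixel counts TP, FP, FN, TN:

* IoU_c = TP/(TP + FP + FN); PA_c = (TP + TN)/(TP + FP + FN + TN).
* MIoU and MPA are unweighted means over all k + 1 = 3 classes
  *including background*.
* DO and DM are the Euclidean pixel distances between true and predicted
  disc and macula centers; per-image DFA error is |predicted − true|.
* Summaries report min/max/average over test images. Metrics are averaged
  per image; a class absent from both masks would receive IoU 1.0 and a
  flag (this cannot occur in valid scenes, which always contain both
  structures).
* Images whose predicted mask lacks a class are recorded as
  `unmeasurable`, counted separately, and excluded from angle and center
  summaries rather than silently dropped.

## Synthetic fundus scenes

Real fundus photographs of the study population are not redistributable,
so the package generates synthetic scenes carrying exact ground truth. A
scene renders a reddish vignetted background, a bright slightly-oval disc
ellipse (semi-axis about 5.5% of frame width) with a soft edge, a radial
Gaussian darkening around the fovea (scale 0.6 of the macula label
radius), dark quadratic-Bezier vessel arcs rooted at the disc (nuisance
texture, never labeled), and i.i.d. Gaussian sensor noise (sigma 6 of 255
by default). The fovea is placed temporal to the disc at a distance
defaulting to 0.29–0.33 of frame width (about 800 px at native scale) and
at an angle drawn from ±10°, covering the physiological DFA range;
left/right laterality mirroring is available but off by default. Centers
are rounded to the integer pixel grid and the stored `true_dfa` is the
exact angle of the rounded centers, so the ground truth chain
(centers → angle) is self-consistent to machine precision; the requested
angle is honored to within the ≤0.5 px/coordinate rounding.

Rasterization uses the pixel-center rule (a pixel belongs to a region iff
its integer-coordinate center satisfies the region inequality), which
makes the 400-px label radius exactly measurable. Feeding ground-truth
masks through the geometric stages recovers the true DFA exactly on these
scenes, so any error in the full pipeline is attributable to the learned
segmentation stage.

What the generator does *not* emulate: real optic-disc texture (cup/rim
contrast), laterality statistics, illumination artifacts, camera optics,
pathology, and inter-grader labeling variability. Passing tests on these
scenes demonstrate that the pipeline's plumbing, geometry and formulas are
correct and that the networks can learn the task; they say nothing about
clinical accuracy on real photographs.

## Desk-scale experiment sizes

The self-contained end-to-end experiment trains the DeepLabv3+ at width
multiplier 0.25 on 64 synthetic 128 x 128 images (57/7 train/validation
after the 9:1 split) for 20 epochs with Adam at learning rate 0.002 —
the package's chosen desk-scale configuration; the default 0.00005 rate is
tuned for publication-scale runs and moves a from-scratch network too
slowly for a 20-epoch budget — and evaluates on 16 held-out images.
Observed results across seeds: held-out MIoU 0.70–0.87, mean DFA error
roughly 2.5–7.5° (occasional runs produce an outlier image whose blob
shape shifts a center by several pixels), disc center error 1–6 px,
macula center error 3–4 px. At this scale the
disc-fovea distance is only ~40 px, so each pixel of macula-center error
costs ~1.4° of angle; the macula dominates the error because its label
boundary has no image contrast (the network must internalize the fixed
label radius). The oracle route (ground-truth masks through geometry +
angle) is exact, bounding the geometric stages' contribution at zero.

## Numerical choices and edge cases

* Minimum enclosing circle: Welzl's move-to-front algorithm on the convex
  hull vertices (the hull's MEC equals the set's); a fixed internal
  shuffle makes the fit deterministic. Collinear/degenerate inputs fall
  back to the widest diameter pair. Containment uses a 1e-7 slack.
* Connected components use 8-connectivity; component ties resolve to the
  first in raster order.
* Coincident disc/macula centers raise an error (angle undefined).
* Scene placement failures (geometry cannot fit in frame) raise a
  `PlacementError`; dataset sampling retries with fresh draws a bounded
  number of times, which preserves determinism because all draws come from
  one seeded generator.
* Batch-norm statistics: momentum 0.1, eps 1e-5; evaluation uses running
  statistics.

## Known limitations

* The synthetic domain is deliberately schematic; no claim of clinical
  validity transfers from it.
* Desk-scale accuracy is limited by geometry (small disc-fovea distance in
  pixels), not by the method; native-scale distances shrink the same
  center errors to fractions of a degree.
* The numpy engine is single-threaded BLAS-bound and intended for small
  and medium runs; publication-scale 512 x 512 training with width 1.0 is
  functional but slow.
* Only normal-eye morphology is modeled; diseased fundi are out of scope.
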