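# Methods

`handage` implements a computer-aided bone-age assessment pipeline for
hand-wrist radiographs: fully unsupervised localization of the hand, a
deterministic cropping/equalization pipeline, and a convolutional regressor
that fuses the patient's gender into the image feature. This note records
the models, the choices that were genuinely open, and what the synthetic
test bed does and does not establish.

## Per-image unsupervised localization

Hand radiographs arrive at widely varying resolutions and contrasts, and the
informative region (the hand) occupies only part of the frame. Rather than
train a detector on annotated boxes, the package fits a small CNN *to each
image individually* by differentiable feature clustering. The network is two
3×3 convolutions (stride 1, same padding, ReLU + per-channel batch
normalization) producing p feature channels, a 1×1 convolution to q response
channels, and a final batch normalization; the per-pixel argmax of the
response vector y_n is the cluster label c_n. Optimization alternates argmax
assignment with SGD (momentum 0.9, lr 0.1, 50 iterations) on

    L = λ · L_sim + μ · L_con,      λ = 4, μ = 1 by default,

where L_sim is the cross-entropy between each pixel's response and its own
argmax label (pulling features inside a cluster together) and L_con is the
L1 difference between horizontally and vertically adjacent response vectors,
an anisotropic total-variation penalty that merges fragmented labels. The
number of distinct surviving labels falls from q (default 90) on its own; no
stopping rule other than the fixed iteration budget is applied.

Numerical choices worth knowing:

* **Probabilities before the logarithm.** Batch-normalized responses can be
  non-positive, so L_sim applies softmax per pixel before the log (with a
  1e-12 guard in the reference implementation of the loss). The argmax
  labels are unchanged by this monotone map.
* **Literal summation footprint.** L_con sums over the (W−1)×(H−1) index
  grid for both the right-neighbour and down-neighbour terms, so differences
  along the last row *and* last column are excluded. The test oracles use
  the same ranges. A full total-variation variant would include them; the
  difference is an O(1/H) boundary term.
* **Per-pixel scaling of the objective.** The exposed loss functions are
  plain sums; inside `segment_image` the optimization objective is
  (λ·L_sim + μ·L_con)/N with N the pixel count. A single global scale keeps
  SGD at lr 0.1 stable across resolutions and leaves the λ:μ balance and the
  minimizer unchanged.
* **Argmax ties** go to the lowest channel index — deterministic and
  testable.
* **Working size.** Images whose longest side exceeds 256 px are downscaled
  for clustering and the label map is mapped back by nearest neighbour;
  this bounds the per-image cost without changing the method.
* The network is freshly initialized (seeded, fan-in-scaled normal) for
  every image; batch normalization uses the single image's own spatial
  statistics, since there is no batch.

The field's kernel sizes, activations and initialization for this clustering
network are not pinned down by the method itself; 3×3 kernels with ReLU are
the minimal standard choice and are configurable.

## Pre-processing pipeline

Segmentation label map → hand crop, in five deterministic steps:

1. **Background removal.** The cluster label owning the most frame-border
   pixels is declared background (radiograph background always touches the
   frame edge); ties go to the lower label. All other labels form the
   foreground mask.
2. **Connectivity analysis.** 8-connected components of the mask, summarized
   (area, tight box, border contact) and sorted by area.
3. **Maximum-area rule.** The largest component is the hand; its bounding
   box is expanded by a 2% margin of each frame dimension (crops retain a
   small border) and clipped.
4. **Crop + global histogram equalization** on 8-bit quantized intensities,
   using the classical CDF remapping with cdf_min normalization (the darkest
   occupied level maps to 0, the brightest to 255). Global rather than
   adaptive equalization: the method calls for plain histogram equalization,
   and global equalization is the parameter-free reading.
5. **Square padding and resize** to the model input side (224/500/700
   supported; smaller sizes used in tests). Padding uses the border median
   as fill so the pad looks like background; the aspect ratio is preserved
   because anisotropic stretch would distort bone shapes.

Coordinates are 0-based, half-open throughout. A pass-through mode (resize
only) implements the "no pre-processing" ablation arm.

## Regression network

The image branch is MobileNetV3-Large exactly as tabulated: a strided 3×3
stem (16 channels, h-swish), fifteen inverted-residual blocks
(1×1 expansion → depthwise k×k → optional squeeze-and-excitation → linear
1×1 projection, skip connection iff stride 1 and matching channels), a 1×1
convolution to 960 channels, adaptive average pooling, and a 1280-wide
feature layer (no batch normalization) with h-swish,
h-swish(x) = x·ReLU(x+3)/6. Expansion widths and SE bottleneck sizes follow
the published MobileNetV3-Large values where the tabulated stack is silent;
the one tabulated divergence from the canonical stack (a 3×3 rather than 5×5
depthwise kernel in the sixth block) is kept as tabulated. SE gates use the
hard sigmoid, so a channel is never amplified.

Gender enters as a 0/1 scalar (male = 1) through a rectified linear
embedding of width 24, concatenated with the image feature to a 1304-dim
fused vector. The prediction stage is a rectified 1304-wide fusion layer
followed by a one-hidden-layer MLP (1304 → 1304 → 1) emitting a single
standardized-age scalar. With this reading the assembled network carries
7,604,905 learnable parameters ≈ 7.6 M, which is what pins the head down: a
single-matrix head (1304 → 1) or a head without the fusion layer yields
≈ 5.9 M, irreconcilable with the stated total. Batch-norm running statistics
are buffers, not parameters, and are excluded from the count; the count is
independent of input size because the backbone is fully convolutional with
adaptive pooling.

Pre-trained ImageNet weights are supported as an optional user-supplied
checkpoint (`use_pretrained` + a weights path); nothing is downloaded, and
random fan-in initialization is the default.

## Training and evaluation

Targets are standardized bone ages Y' = (Y − μ)/σ with μ, σ computed from
the **training split only**; predictions are destandardized before any
reported number, and errors are mean absolute error in months, printed to
one decimal. The loss is the mean squared error on Y', minimized by SGD with
momentum 0.9, batch size 10, for up to 160 epochs, the learning rate decayed
tenfold every 30 epochs from a base of 0.01 (the base rate is not pinned
down by the method; 0.01 is a standard fine-tuning magnitude and
configurable — the 0.1 figure belongs to the clustering stage).
Augmentation (random crop 90–100%, rotation ±10°, contrast 0.9–1.1×,
brightness ±0.1) applies to training images only; evaluation uses a
deterministic resize. The checkpoint with the best validation MAE is
retained; when no validation split exists the final parameters stand.
Datasets are split 7:2:1 train/validation/test by a seeded shuffle and
contiguous cuts at the 70%/90% quantile indices, with no stratification.

Ablation axes are first-class configuration: gender embedding on/off (off
shrinks the fused width to 1280), pre-processing on/off (pass-through
resize), pre-trained initialization on/off, and input size.

## Numerical engine

The networks run on a compact reverse-mode autodiff engine over numpy
arrays (`handage.nn`): dense convolution by im2col + GEMM, depthwise
convolution by einsum over sliding windows, batch normalization with exact
batch-statistics gradients, fused softmax cross-entropy, and SGD with
classical momentum. Float32 is the working precision; every operation also
runs in float64, which is how the test suite checks all layer gradients
against central finite differences (relative error ≤ 1e-4, typically
≤ 1e-7).

## Synthetic test bed

The generator emulates the properties of pediatric hand radiographs that
the pipeline actually relies on: one bright, *connected* hand (palm ellipse
plus five fanned finger ellipses at anatomical proportions — finger width
≈ 0.1 and length ≈ 0.42 of the hand extent — rotated by a seeded angle) of
maximal area on a darker background, Gaussian noise, variable resolution
(96–192 px) and contrast, and 1–3 small bright distractor blobs disjoint
from the hand. Bone ages are truncated-normal per gender on [0, 240] months
(male mean 132, female mean 120, sd 28), so gender carries real signal for
the regressor, and metadata follows the `id,boneage,male` CSV convention.

What it does not emulate: carpal/epiphyseal anatomy, maturity-stage
appearance, scanner artefacts, or any true age–image relationship beyond the
gender shift. Passing tests therefore establish that the machinery is
correct — losses match their formulas, localization recovers the bright
connected region (box IoU ≥ 0.7 on ≥ 18/20 scenes at 128×128), training
optimizes what it should (8-sample overfit to ≤ 10% of the initial MSE in
200 steps) — not that clinical-grade MAE (≈ 5–6 months on real datasets of
10⁴ images with GPU-scale training) is reproduced; that is outside this
package's scope.

Problem sizes used by the default test suite were chosen to keep a full run
on one CPU core in the minutes range: clustering tests at 48×48 with q = 8,
the localization recovery check at 128×128 with q = 32 (the label budget
scaled to the frame, 50 iterations), and the training smoke at 96×96 with
200 full-batch steps and learning-rate decay disabled within the run (with
one step per epoch, the 30-epoch decay schedule would silence most of the
prescribed steps).

## Known limitations

* Pure-numpy execution is single-threaded GEMM-bound; throughput is fit for
  testing and small studies, not for training on 10⁴ real radiographs.
* The background rule (most border pixels) assumes the hand does not
  dominate the entire frame border.
* Per-image clustering is stochastic in its initialization: a pathological
  seed can merge the hand with background at very low contrast. The
  localization test quantifies this (≥ 18/20 scenes).
* The equalization is global; strongly non-uniform illumination would argue
  for an adaptive variant, which is deliberately not implemented.
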