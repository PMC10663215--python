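# Methods

`caneseg` quantifies the quality of harvested raw sugarcane from overhead
images in two stages: a semantic segmentation network assigns every pixel to
one of five classes (background, cane, broken cane, top, leaf), and a
surface-density mass model converts the resulting per-class pixel counts
into grams and then into two quality ratios. This note records the models,
the assumptions behind them, the numerical choices, and what the synthetic
data used for testing does and does not demonstrate.

## The surface-density mass model

For a material class *i* with pixel count `P_i`, the estimated mass is

    M'_i = mu_i * P_i

where `mu_i` is the class's mean surface density in grams per pixel,
obtained by fitting a Gaussian to the per-image densities `M_i / P_i` of a
calibration set. The two quality ratios are mass fractions:

    R_B = M_B / (M_C + M_B)                       (breakage)
    R_I = (M_T + M_L) / (M_C + M_B + M_T + M_L)   (impurity)

with C, B, T, L denoting cane, broken cane, top and leaf. The same formulas
apply to measured and estimated masses; ratios are stored as fractions in
[0, 1] and rendered as percent only at presentation time. The packaged
reference densities are 1.52e-3, 7.4e-4, 8.8e-4 and 3e-5 g/pixel for cane,
broken cane, top and leaf; any fitted `SurfaceDensityModel` can replace
them.

Key assumptions: surface density is constant within a class *per image* but
varies between images (hence the Gaussian distribution over images); pixel
count is proportional to projected area, which is proportional to mass for
material of roughly constant thickness. Leaf density is ~50x smaller than
cane density, so leaf segmentation errors have little effect on the ratios.

Design choices where the procedure was open:

* **Gaussian fit.** Default is moment matching (sample mean and standard
  deviation of the per-image densities); an alternative mode least-squares
  fits the Gaussian PDF to the normalized frequency histogram. The fit
  quality R² always compares the fitted PDF to the normalized histogram at
  bin centers; bin count defaults to Sturges' rule and is configurable.
* **95% CI selection** is marginal per class: a sample is kept only if, for
  every class present in it, its density lies within mu ± 1.96 sigma. Joint
  (ellipsoidal) filtering would be the alternative; marginal filtering is
  simpler and matches how univariate outliers are screened in practice.
* **Division by zero.** A sample with zero total mass raises a typed
  `UndefinedRatioError` instead of returning NaN; silent NaNs would corrupt
  batch evaluation. A zero numerator with a positive denominator is a valid
  ratio of 0.
* **Evaluation.** `evaluate_ratio_tables` reports per-sample relative
  errors `|measured − estimated| / measured`, their arithmetic mean
  (computed on unrounded values), and an OLS fit of estimated on measured
  with the standard ANOVA decomposition (df 1 and n−2, significance from
  the F distribution, via scipy).

## The segmentation network

The network is a DeepLabv3+-style encoder-decoder sized for edge
deployment (~3.5M parameters in the full configuration):

* **Backbone**: the first eight layers of MobileNetv2 (stem plus seven
  inverted-residual stages, ending at 320 channels). The stage plan is
  (t, c, n, s, r) = (1,16,1,1,1), (6,24,2,2,1), (6,32,3,2,1), (6,64,4,2,1),
  (6,96,3,1,1), (6,160,3,1,2), (6,320,1,1,5): the 160-channel stage trades
  its stride for dilation 2 and the last stage uses dilation 5, keeping the
  output stride at 16 while enlarging the receptive field. An inverted
  residual expands channels by t with a 1x1 convolution, filters with a
  3x3 depthwise convolution (carrying stride/dilation), and projects
  linearly to the output width; the shortcut is added iff stride is 1 and
  input and output widths match. Stride 2 combined with dilation > 1 is
  rejected as undefined.
* **ASPP_DS head**: parallel branches — a 1x1 convolution, three 3x3
  depthwise-separable convolutions at dilations (4, 8, 12), a global
  average-pooling branch broadcast back, and a strip-pooling branch —
  concatenated and fused to 256 channels. Strip pooling mean-pools the
  input to CxHx1 and Cx1xW, expands each strip with a kernel-3 1-D
  convolution along its long axis, broadcast-sums, fuses with a 1x1
  convolution and gates the input through a sigmoid. The long, thin
  pooling windows suit the elongated cane and leaf geometry.
* **Coordinate attention**: per-channel pooling along width and height,
  a shared 1x1 convolution + batch norm + ReLU with channel reduction 32
  (floor of 8), then per-direction 1x1 convolutions and sigmoids giving
  gates a_h (CxHx1) and a_w (Cx1xW); output is x · a_h · a_w. Applied
  after the ASPP fusion and/or to the low-level features entering the
  decoder, per configuration.
* **Decoder**: low-level 24-channel stride-4 features projected to 48
  channels, concatenated with the 4x-upsampled head output, refined by a
  depthwise-separable 3x3 convolution to 256 channels, classified 1x1,
  and upsampled 4x back to input resolution.

Seven ablation variants toggle these pieces (`base`, `M`, `MDS`, `MC1`,
`MC2`, `MC`, `MDSC`); `base` uses the stock backbone strides (output
stride 32) and a plain pyramid at dilations (6, 12, 18) with no strip
pooling or attention.

Open-design choices: head widths 256/48 (the standard DeepLabv3+ values);
output stride 16 by default, with 8 available by converting the 64-channel
stage to stride 1 + dilation; ReLU6 inside inverted residuals and ReLU
elsewhere; batch normalization after every convolution except the final
classifier; bilinear upsampling without corner alignment and
nearest-neighbor mask resizing; Kaiming-normal (fan-out) weight
initialization with all randomness behind one seed. Class index order is
fixed: 0 background, 1 cane, 2 broken cane, 3 top, 4 leaf.

### Numerical engine

The network runs on a small reverse-mode autodiff core built on numpy
(float32 throughout): tensors with a dynamically built tape, convolutions
evaluated as im2col plus one BLAS matmul (a pure view for 1x1 kernels) or
as a per-tap loop for depthwise kernels, batch normalization with running
statistics (variance accumulated in float64), separable bilinear
interpolation expressed as two small dense interpolation matrices, and
Adam. Gradients of every operation are verified against central finite
differences in the test suite, and a single-channel convolution is checked
against scipy's `correlate2d`.

Two numerical edge cases worth knowing: batch normalization of the global-
pooling branch (1x1 spatial extent) has degenerate batch statistics at
batch size 1 — the gradient of the preceding convolution is exactly zero
there, so training should use batches of at least 2; and probabilities are
clamped at 1e-7 before any log (Dice terms are smoothed with 1e-6).

## Losses and metrics

Class frequencies are heavily imbalanced (background dominates; broken
cane is rare), so training combines focal loss,
`-alpha_t (1 - p_t)^gamma log p_t` with gamma = 2 and a uniform
alpha = 0.25 by default (a per-class alpha vector is accepted), with a
multi-class soft Dice loss `1 - sum_j 2 W_j <g_j, p_j> / (|g_j|² + |p_j|²)`
whose class weights are normalized to sum to 1 (uniform by default; a
literal 1/j-by-class-position mode and an auditable log-transformed
variant exist but are not recommended for training).

Evaluation accumulates a pixel confusion matrix and derives per-class
IoU = P_ii / (row_i + col_i − P_ii), mIoU and mPA as unweighted means over
all classes *including background* — five classes here. The 5-class
convention is deliberate: the published per-class IoUs of every comparison
model reproduce the published mIoU only when background is included in the
mean. Classes absent from both prediction and ground truth are excluded
from the means and flagged; per-class accuracy is undefined (and excluded)
for classes with no ground-truth pixels. Parameters are counted as
trainable weight elements; FLOPs are counted analytically per layer at
batch 1 (2 FLOPs per multiply-accumulate; convolutions, linear maps and
normalizations), replayed over a real forward pass so each layer reports
at the spatial size it actually sees. Inference time is logged best-effort
and never asserted — it is hardware-bound.

## Synthetic data: what it emulates and what it does not

The calibration imagery of harvested cane is not publicly deposited, so
the package generates structurally similar scenes: elongated
slightly-curved cane ribbons (width ~5–8% of the image side), short jagged
broken-cane fragments, tapered top wedges and thin curved leaf strips
(~1.4–2.4% wide) on a near-black background, drawn in random order with
later objects occluding earlier ones. Images render each class with a
distinct noisy color plus a low-frequency illumination gradient; masks use
the five-class palette (0,0,0), (128,0,0), (0,0,128), (0,128,0),
(128,128,0). Per-class masses are pixel count times a truncated-normal
density draw, so a sigma = 0 model yields masses exactly mu times pixels —
the basis of the exact end-to-end closure tests.

The calibration-style mass dataset draws pixel counts uniformly per class
(defaults 30–120k cane, 10–60k broken cane, 5–50k top, 5–80k leaf, matching
plausible occupancy of a ~512² scene) and Gaussian densities around the
reference means with spreads (1.2e-4, 1.8e-4, 2.2e-4, 0.9e-5 g/pixel):
cane is concentrated, the other classes more scattered. Within one sample
the class densities share a common standardized deviation
(`class_correlation`, default 1.0), modeling a per-image packing/viewing
factor that moves all classes together; this reproduces an overall ~95%
retention (about 285 of 300) under marginal per-class 95% CI filtering,
which independent class draws cannot (they would retain ≈ 0.95⁴ ≈ 81%).
A side effect of perfect correlation is that the per-class standardized
histograms — and hence their fit R² — coincide.

The six augmentations are: rotation and affine (bilinear on the image,
nearest on the mask, exposed borders filled with background), fog
(`image' = t·image + (1−t)·A` with transmission t in [0.6, 0.95] and a
bright atmospheric value A), Gaussian noise, median filtering (image
only), and cutout, which zeroes an image patch *and* relabels it
background in the mask so labels stay consistent with appearance.
Datasets are split 6:2:2 by largest-remainder rounding; the augmentation
factor counts the original (factor 10 means 1 original + 9 augmented
copies), so 910 originals give 546/182/182 and 5460/1820/1820 after
augmentation. On-disk layout follows the VOC convention (`JPEGImages/`,
palette-indexed `SegmentationClass/` PNGs, `ImageSets/Segmentation/*.txt`);
masks round-trip bit-exactly.

What passing on synthetic scenes shows: the architecture has the capacity
and gradient path to learn this segmentation task; the pixel→mass→ratio
chain is exact when segmentation and densities are exact; the fitting,
filtering and evaluation statistics behave as specified. What it does not
show: performance on real conveyor imagery — real cane has texture,
specularity, soil, motion blur and inter-class ambiguity (broken cane vs
cane ends) that the renderer does not model, and the published accuracy
numbers on the real dataset are not reproducible here.

## Training protocol and problem sizes

The reference protocol is Adam at learning rate 1e-4 (constant by default,
cosine decay available), batch size 6, 100 epochs, per-epoch reshuffling,
images resized bilinearly and masks by nearest neighbor to the configured
input size (256, 512 or 768), best-validation-mIoU checkpointing. The
batch size auto-reduces with a warning on datasets smaller than the batch.

The capacity check used by the tests and the acceptance script trains the
full variant on 8 synthetic 256×256 scenes with Adam at 1e-2, batch 4, and
stops once training mIoU (computed in train mode, i.e. with batch
statistics, checked every 10 steps) reaches 95%, capped at 200 optimizer
steps — sizes chosen so the whole run fits comfortably in a CPU-only test
session while still exercising every layer's forward and backward path.
Unit and contract tests run the network at 128–768 px on untrained seeded
weights.

## Known limitations

* CPU-only numpy execution: roughly 1 s per 256² image for a training
  step; practical for tests and small calibrations, not for full-scale
  training runs.
* The renderer is deliberately schematic (see above); headline accuracies
  on real data are out of reach by construction.
* mPA's published class-inclusion convention cannot be verified from
  printed values (only mIoU can); the package applies the same 5-class
  convention to both.
* Checkpoints store weights by deterministic module order; they are tied
  to the architecture configuration they were saved with (the config
  travels as a JSON sidecar and is restored first).
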