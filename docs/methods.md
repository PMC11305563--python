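# Methods

## Problem setting

The package detects cattle instances and their 16 skeleton keypoints (head
top, neck, spine, coccyx, and thigh root / knee / hoof per leg) in RGB images
with a single-stage anchor-free network, and scores predictions with object
keypoint similarity (OKS).  Everything runs on CPU: the tensor layer is a
small numpy reverse-mode autodiff core (`cattlepose.nn`) providing exactly the
operations the models need (im2col convolution, transposed convolution with
kernel = stride, batch normalization, SiLU/ReLU/sigmoid/softmax, max pooling,
nearest upsampling, concatenation/slicing, reductions).  Every backward pass
is validated against central finite differences in the test suite.

## Architectures

**Baseline.**  n-scale CSP backbone — two stride-2 stems, four C2f stages
(depths 1/2/2/1 after the 1/3 depth multiplier), SPPF — feeding a PAN neck
(nearest ×2 upsample, concat, C2f on both paths) and a decoupled head.  Per
grid cell on P3/P4/P5 the head predicts a 16-bin discrete distribution per box
side (collapsed to its expectation at decode time), one class logit, and
16 × (x, y, visibility) keypoint values using the cell-relative
(2p − 0.5 + center)·stride convention.  Channel widths follow the width
multiplier 1/4 with a 1024-channel cap and rounding to multiples of 8.  The
assembled model holds 3,274,403 learnable scalars (3.27 M) and costs
9.09 GFLOPs at 640×640 (batch 1, one multiply-accumulate counted as two
floating-point operations, convolutions only — batch norms and activations are
negligible and excluded, matching the convention of common profilers).

**Improved.**  Two changes, both leaving the head untouched:

1. *SimAM* after the C2f block of each stage feeding the P3/P4/P5 taps
   (before SPPF at P5).  Statistics are pooled over all M = H·W neurons of a
   channel of a single sample — never across a batch — with regularizer
   ω = 1e-4.  The operator holds no parameters, so the count stays 3.27 M
   when it is inserted into the baseline.
2. *EfficientRepBiPAN neck.*  Top-down: a 1×1 reduce layer on P5, a BiFusion
   unit blending the reduced deep map (learned 2×2 transposed-convolution
   upsample), the current level (1×1 projection) and the next-shallower
   backbone tap (1×1 projection + stride-2 3×3 conv), then a RepBlock;
   repeated down to P3 (whose BiFusion taps the stride-4 backbone stage).
   Bottom-up: stride-2 conv, concat with the same-level reduce output, and a
   RepBlock, back to P5 stride.

The neck's internal widths are not externally fixed; the committed reference
configuration pins them to (64, 32, 56, 128) channels for the top-down-P4,
top-down-P3, bottom-up-P4 and bottom-up-P5 stages with RepBlock depths
(4, 4, 5, 5).  This configuration was frozen once and yields 3,111,283
parameters (3.11 M) and 8.06 GFLOPs at 640 — 0.16 M parameters and ~1.0 GFLOP
below the baseline.  Parameter and FLOP counts refer to the as-built
(multibranch) topology; fusing the RepBlocks lowers both.

**Reparameterization.**  Each RepVGG unit fuses BN into each branch
(W′ = W·γ/√(σ²+ε), b′ = β − γμ/√(σ²+ε)), embeds the 1×1 branch and the
identity branch (a Dirac kernel; present only when stride 1 and equal channel
counts) as 3×3 kernels, and sums.  Tolerances: single unit < 1e-5, whole
network < 1e-4 absolute output deviation — the slack covers 32-bit
accumulation order differences between the fused and multibranch forward
passes.  Fusion requires inference mode (frozen BN statistics); fusing twice
is a state error.

**FLOP counting.**  Convolution cost scales exactly with output area, so the
model is profiled once at 64×64 and rescaled to the requested input size; the
test suite asserts the rescaling is exact.

## Evaluation protocol

OKS uses s = √(ground-truth box area) as the object scale and a uniform decay
constant k = 0.1 for all 16 keypoints (per-keypoint constants for cattle are
not established; the vector is configurable).  Both v = 1 (occluded but
labeled) and v = 2 (visible) ground-truth flags count as observed.  Matching
is greedy: predictions in descending score claim the unclaimed ground truth of
maximal OKS; unmatched predictions score 0.  AP at threshold t is implemented
literally as the fraction of matched detections with OKS ≥ t, pooled over all
images (not a precision–recall integral, and not per-image averaged);
AP₀.₅:₀.₉₅ is the exact mean of the ten thresholds 0.50–0.95.

## Synthetic data

The generator renders flat-shaded quadruped silhouettes (trunk and head
ellipses, limb quads, joint disks) over low-frequency textured backgrounds.
It emulates the variation factors of farm imagery — 1–3 instances per image;
large/small instances at 45–75 % / 10–25 % of image height; bright/dim
lighting (dim = 0.35 intensity scale plus additive noise, both repo
constants); front/side/back views with view-dependent self-occlusion
(far-side limbs v = 1 in side view, head top v = 1 from behind); vertical
fence bars that demote covered keypoints to v = 1; edge truncation that
removes out-of-frame keypoints (v = 0).  Because every keypoint disk is part
of the drawn silhouette, a v = 2 keypoint provably lies on its instance's
rendered foreground.  Annotations are emitted in both supported formats with
a factor-tag sidecar, and generation is byte-deterministic per seed.

What it does **not** emulate: breed appearance, barn backgrounds,
photometric realism, animal-to-animal shape variation beyond the jittered
template.  Tests passing on these scenes validate geometry, bookkeeping and
optimization behaviour — not detection accuracy on real farm imagery.

The pseudo-predictor displaces visible keypoints with isotropic Gaussian
noise of standard deviation τ, for which E[OKS] = 1/(1 + τ²/(s²k²)) under
uniform k; the Monte-Carlo agreement of the metric stack with this closed
form (3 standard errors at 10,000 draws) is the core metric-validation
oracle.

## Training

SGD with momentum 0.937 and weight decay 5e-4 (convolution weights only), in
three parameter groups.  Warm-up is linear over the first 3 epochs — bias
groups start at 0.1, all others at 0 — reaching the initial rate 0.01, then
the rate decays linearly to 1e-4 at the final epoch.  (A warm-up rate of 0.1
applied to *all* groups would contradict restoring the initial rate 0.01
afterwards, so 0.1 is taken as the bias warm-up rate, the convention of the
anchor-free family.)  Batch size 32; a simple 2×2 mosaic augmentation is
disabled for the final 10 epochs.

Positive assignment is center-cell: each instance supervises the one cell
containing its box center on the finest level whose 16-bin range can
represent the box.  This is deliberately simpler than task-aligned
assignment; it keeps the loop transparent and fast at toy scale and exercises
every architectural component (the criterion the loop exists to serve).  The
loss combines binary cross-entropy class/objectness (gain 0.5), L1 on the
expected box sides plus two-bin distribution cross-entropy (gains 7.5 / 1.5),
an OKS-kernel keypoint-location term (gain 12) and keypoint-visibility BCE
(gain 1).  Two numerical choices matter: class logits are initialized to a 1 %
prior so untrained pyramid levels stay quiet, and the location term adds a
small scale-normalized quadratic (0.1·d²/area) because the Gaussian kernel's
gradient vanishes far from the target.

The committed smoke-test scale is 200 scenes at 64×64 with width multiplier
1/8 for 50 epochs (≈2 minutes on one CPU core); at this scale the loss falls
monotonically in 10-epoch block means and validation AP is small but nonzero —
the run demonstrates end-to-end optimization and fusion-invariance of the
metrics, not accuracy.

## Degenerate inputs and tie-breaks

Single-neuron channels (M = 1) are rejected by SimAM (variance undefined).
OKS is undefined without a visible ground-truth keypoint and raises.  Match
ties on equal scores are broken by input order.  Zero-area boxes are rejected
at conversion.  Inputs not divisible by 32 are rejected by the backbone.
Empty factor subsets are omitted from stratified reports with a warning.

## Known limitations

* The numpy core is single-threaded apart from BLAS matmuls; full-resolution
  training is out of reach, which is why accuracy-level results are not
  claimed anywhere.
* `ConvTranspose2d` supports only kernel = stride (sufficient for the ×2
  upsampler used here).
* The s/m/l/x width/depth scalings are expressible in `ModelConfig` but only
  the n-scale is tested.
* Mosaic augmentation is a simplified 2×2 paste; HSV and affine augmentation
  are not implemented.
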