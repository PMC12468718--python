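# Methods

This note documents the models, algorithms and design choices the package
implements, the parameters that matter, what the synthetic phantoms do and
do not emulate, and the numerical conventions that make every run
bit-reproducible.

## Preprocessing chain

MRI slices suffer from multiplicative low-frequency intensity inhomogeneity
(coil bias) and additive acquisition noise.  The enhancement chain runs
three stages in a fixed order; each maps an 8-bit grayscale image to an
8-bit grayscale image, deterministically, with reflection padding at
borders.

**CLAHE.**  The image is divided into a tile grid (default 8×8; reflection
padding when the grid does not divide the image).  Each tile's histogram is
clipped at `clip_limit` times the uniform bin height (default 2.0), the
excess mass is redistributed uniformly over all 256 bins in a single pass,
and the tile mapping is `I' = round((L−1)/MN · Σ h(k))` with `MN` the tile
pixel count.  Outputs are bilinearly interpolated between the four nearest
tile mappings.  With one tile and a non-binding clip limit this reduces
exactly to plain histogram equalisation, which the tests pin.

**Non-local means.**  Each pixel becomes the weighted mean of its search
window (default radius 5), the weight of a neighbour being
`exp(−‖P(x)−P(y)‖²/(2h²))` over 3×3 patches of intensities normalised to
[0, 1]; `h` defaults to 1.0, the midpoint of the 0.8–1.2 range that suits
this normalisation.  Weights are normalised to sum to one, so a constant
image is a fixed point.

**Kuwahara.**  For a `w×w` window (default 5) the four `⌈w/2⌉`-square
corner quadrants share the centre row and column.  Standard mode outputs
the mean of the minimum-variance quadrant; variance comparison uses the
exact integer quantity `n·Σx² − (Σx)²`, so ties are real ties and are
broken deterministically toward the lowest quadrant index (NW, NE, SW, SE).
Linear mode blends the quadrant means with weights `(σ² + 10⁻⁶)^(−q)`
(default sharpness q = 8) normalised to one, which removes the block-selection
instability of the standard filter at near-tied variances; as q → ∞ it
approaches the standard filter.  The blend is accumulated in a fixed
left-to-right quadrant order so the float result is reproducible to the bit.

**Contrast measurement.**  The preprocessing benefit is quantified with the
Michelson contrast `(L_max − L_min)/(L_max + L_min)` of the tumor
neighbourhood, using robust 5th/95th percentiles over the region within 16
pixels of the lesion.  This measures the local dynamic range separating a
lesion from its surround — the quantity local histogram equalisation
targets.  A mean-ratio two-region contrast is deliberately not used as the
headline measure: a multiplicative bias field scales lesion and surround
equally, leaving that ratio invariant, so it cannot register the benefit.
Both forms are exposed (`local_michelson_contrast`, `michelson_contrast`).
At the native 256×256 scale the full chain raises the local contrast on all
twenty seeded phantoms the acceptance script generates.

## Attention operators

**Scaled tanh gates.**  All attention weights are `tanh(α·x)` with the
scale α (default 1.0) exposed in configuration; gates therefore lie in
(−1, 1).

**Adaptive channel attention (ACA).**  Global average pooling produces a
channel vector; a single 1D convolution over the channel axis (zero
same-padding) followed by the scaled tanh yields per-channel gates.  The
kernel length adapts to the channel count as
`k = odd(⌊|log₂(C)/γ + β/γ|⌋)`, γ = 2, β = 1 (so C = 64 → 3,
C = 256 → 5): nearby channels interact directly, and the interaction range
grows logarithmically with width at negligible parameter cost.

**Fully connected channel attention.**  The classical squeeze-and-excite
form with a reduction-r bottleneck (`Ua: C×⌈C/r⌉`, `Ub: ⌈C/r⌉×C`, default
r = 4) is provided as an alternative operator; the default assembly uses
the convolutional ACA.

**Gate form.**  Channel gates multiply features as `x·(1+ω)` (residual
form), so a zero-initialised gate is exactly the identity and training
starts from the ungated network; channel-gain values then lie in (0, 2).
Triplet attention uses the literal `x·ω` product of its defining equation.
Both forms are selectable.

**Dimensional-space triplet attention (DTA).**  Three branches each reduce
one axis of the H×W×C tensor (width, height, or channels) by stacking max-
and average-pooling as a two-channel map over the remaining plane,
convolving it (single 7×7 kernel, two input channels, zero same-padding),
and gating the input with the scaled-tanh output broadcast over the reduced
axis.  The branch outputs, permuted back, are averaged with equal 1/3
weights.  The branches therefore model height–channel, width–channel and
height–width interactions respectively.

## Network variants

Four nested U-shaped architectures form an ablation ladder; each variant's
weight set strictly contains the previous one's, so parameter counts are
strictly nested:

1. `unet` — stages of two (3×3 conv → batch norm → ReLU) blocks; 2×2
   max-pool between encoder stages; stride-2 transposed convolutions,
   skip concatenation and a stage block in the decoder; a final 1×1
   convolution emits the class scores.
2. `unet_res` — stages become residual: `proj(x) + cb₂(cb₁(x))` with a 1×1
   projection when channel counts differ.  Residual shortcuts keep
   gradients flowing in deep stacks (verified by a depth-5 gradient test).
3. `unet_res_aca` — an ACA gate follows every encoder stage (including the
   bottleneck), refining channel weighting where resolution is low.
4. `arunet` — additionally the stem is wrapped in a context information
   transmission (CIT) block, and every decoder stage ends with DTA.

**CIT.**  The stem's primary block produces the full-resolution map Q₁;
max-pooling gives Q₂; the pooled branch is refined by scaled tanh → ACA →
scaled tanh and upsampled (nearest-neighbour, restoring the grid the sum
requires) to give Q₃; the stage output is `R₁ = Q₁ + Q₃`, while Q₂ itself
is forwarded down the encoder.  The stem therefore transmits
attention-refined context downward without an extra convolution, and the
skip connection to the decoder carries R₁.

**Defaults.**  Reference scale is depth 5, base width 64 (doubling per
stage), matching the ~30 M-parameter regime of full-scale runs; the tests
and the acceptance harness use a `--tiny` configuration (depth 3, base
width 8, 31,574 parameters) chosen so the whole study runs in minutes on
one CPU.  Convolutions are He-uniform initialised, batch norm starts at the
identity (γ=1, β=0) and uses batch statistics in training / running
statistics at inference, channel-attention kernels start at zero (identity
gate), and all initialisation is driven by the model seed.

## Training protocol

Splits are stratified per class at 6:2:2 (train/validation/test).  The loss
is class-weighted categorical cross-entropy over pixels,
`−(1/N) Σ w_t log p_t`, probabilities clamped at 10⁻¹².  Class weights are
inverse-frequency, normalised to mean 1, computed **over the tumor classes
only, with the background class pinned at weight 1**: the weighting exists
to counter the imbalance between tumor types, and a literal inverse pixel
frequency including background (≈97 % of pixels) would give the background
a weight near 0.007 and drive the network to paint tumor everywhere — a
failure mode the tests document.  Mini-batches are class-balanced: every
batch holds ⌊B/C⌋ examples per class with the remainder rotating
deterministically, drawing without replacement until a class is exhausted,
then reshuffling.  Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸)
at learning rate 10⁻⁴ by default, batch size 8 (6 is equally defensible
and configurable), at most 40 epochs.

Two monitoring criteria are deliberately independent: training stops early
when validation **loss** fails to improve for `patience` (default 10)
consecutive epochs, while the retained checkpoint is the epoch with maximal
validation **weighted F1** (support-weighted mean of per-class pixel F1).

The short learnability harness (200 optimisation steps on sixty 64×64
phantoms) uses learning rate 10⁻³: a 200-step budget is a different
schedule regime from the 40-epoch reference protocol, and 10⁻³ is the
standard Adam rate for short from-scratch smoke runs.  Its headline
quantity, foreground DSC, is computed from the marginal tumor probability
(`1 − p_background > 0.5`) rather than the 6-class argmax: with five
visually similar lesion classes the argmax splits tumor probability mass
and under-segments boundaries even where the total tumor probability
exceeds one half, so marginalisation is the correct estimator of the
binary tumor-vs-background quantity.

## Evaluation metrics

Per class, one-vs-rest over pixels: accuracy, precision, recall, F1,
IoU = TP/(TP+FP+FN), DSC = 2TP/(2TP+FP+FN).  Per class F1 ≡ DSC and
DSC = 2·IoU/(1+IoU); both identities are enforced by property tests (F1 is
computed as 2·Precision·Recall/(Precision+Recall) — the only form
consistent with the F1 ≡ DSC identity).  Ratios with zero denominators are
reported as 0 with a `degenerate` flag, never NaN, so aggregation over
empty classes is stable.  Aggregates are support-weighted (the checkpoint
criterion) and macro means.  An image-level classification view (majority
non-background class per mask) is available as a secondary report.

## Synthetic phantoms

Phantoms emulate the *structure* of an axial brain MRI dataset catalogued
folder-per-class (Normal plus five tumor classes), not its radiology: an
elliptical head with smooth Gaussian-filtered texture, a class-styled tumor
blob (classes differ in intensity offset 50–90 gray levels, eccentricity
1.0–1.8, boundary irregularity 0.08–0.30 and lobe count, so they are
learnably distinct), a multiplicative bias field built from 2–4 low-order
cosine terms at amplitude 0.3, and Gaussian noise at σ = 5 gray levels.
The mask is the exact generating blob carrying the class index (0 =
background; Normal has an empty mask).  Default image size is 256; tests
use 64 for speed.  Tumor radii default to 10–18 % of the image size.

Because blobs are bright, compact and noise is modest, passing the
learnability test shows the training loop, gradients and attention wiring
work end to end — it does not show that the architecture handles real
tumor heterogeneity, infiltrative boundaries, multi-modal sequences or
annotation noise.  Likewise the contrast-benefit test demonstrates the
direction of the preprocessing effect under synthetic bias, not its
magnitude on clinical data.

## Numerical conventions

Everything runs in float64 on a single CPU.  Rounding to gray levels is
`floor(x + 0.5)`.  Kuwahara quadrant selection and CLAHE histograms use
exact integer arithmetic.  Max-pool gradients share ties equally.  The
autograd engine's every operator is verified against central finite
differences; the attention layers are additionally cross-checked against
framework-free functional implementations, which in turn match nested-loop
references.  Two runs with identical seeds produce byte-identical history
CSVs, checkpoints and generated datasets.

## Known limitations

* The engine is an interpreter over numpy: fine at desk scale (the 200-step
  tiny run takes ~90 s), not meant for 30 M-parameter training.
* Only 2× pooling/upsampling geometries are provided; input sizes must be
  divisible by 2^(depth−1).
* The phantom generator makes no attempt at MRI physics (no partial volume,
  Rician noise, or sequence-dependent tissue contrast).
* Batch-norm behaviour with batch size 1 in training mode is degenerate
  (variance 0); use batch sizes ≥ 2 for training.
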