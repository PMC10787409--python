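# Methods

## Problem

Segmenting the supraspinatus muscle-tendon unit in oblique-coronal shoulder
MRI is hard for classical methods because the target is thin, elongated and
crescent-shaped, and because adjacent muscles (trapezius, deltoid) have
nearly the same grayscale values, which blurs the boundary signal.  The
package implements an encoder-decoder segmentation network designed for
this setting, together with the full experimental scaffolding around it:
a synthetic phantom benchmark, subject-level data handling, a fixed
training recipe, pixel-count metrics, and a five-variant ablation harness.

## Model

The network follows the LinkNet design: a residual encoder, additive skip
connections, and a light transposed-convolution decoder.

**Encoder.** A ResNet-18 or ResNet-34 feature extractor: a 7x7 stride-2
stem convolution, a 3x3 stride-2 max pool, then four residual stages with
block counts (2,2,2,2) at depth 18 or (3,4,6,3) at depth 34 and widths
64/128/256/512.  Total downsampling factor is 32, so input sides must be
divisible by 32; a 512-pixel image produces a 16 x 16 x 512 bottleneck.
Weights are He-normal initialised from a seeded generator; no pretrained
weights are used or required.

**Channel attention (optional).** A squeeze-excitation gate on each of the
three skip connections, applied at the junction immediately before the
additive fusion with the decoder feature: global average pooling squeezes
each channel to a scalar, a two-layer MLP with reduction r = 16 and a
logistic output produces a per-channel gate in (0, 1), and the skip feature
is rescaled channel-wise.  Because every gate is strictly below one, the
gated feature never exceeds the input in magnitude — a property the tests
assert.  r is configurable and must divide the gated widths (64, 128, 256).

**DenseASPP bridge (optional).** Between encoder and decoder, a densely
connected atrous spatial pyramid.  Branch *i* consumes the concatenation
of the bottleneck with the outputs of branches 1..*i*-1; each branch is a
1x1 reduction to 128 channels followed by a 3x3 convolution with dilation
d_i (padding = dilation, so spatial size never changes) emitting 64
channels.  Default rates are (3, 6, 12, 18, 24); a (1, 2, 4, 8) preset in
the D-LinkNet style is available by configuration.  A final 1x1 projection
maps the dense concatenation back to 512 channels and is added residually
to the bottleneck.  The inter-branch budget (reduce 128, growth 64) keeps
the bridge much smaller than the encoder.

**Decoder.** Four LinkNet decoder blocks (1x1 reduce to C/4, 3x3
transposed convolution stride 2, 1x1 expand to the next stage's width);
after the first three blocks the corresponding (optionally gated) skip is
fused by elementwise addition.  The head is a stride-2 transposed
convolution to 32 channels, a 3x3 convolution, a 1x1 convolution to one
channel, and a logistic squashing, giving a per-pixel foreground
probability at input resolution.

**Ablation variants.**  `baseline` = depth-18 encoder, no attention, no
bridge; `scheme1` = depth-34 encoder; `scheme2` = scheme1 + attention;
`scheme3` = scheme1 + bridge; `full` = both.  Parameter counts are
strictly ordered baseline < scheme1 < {scheme2, scheme3} < full, and
toggling a flag adds exactly one named parameter subtree (`attention.*` or
`bridge.*`), which the harness verifies by parameter-name diff.

## Numerical backend

The networks run on a compact define-by-run automatic-differentiation
engine over NumPy (`cuffseg.nn`).  Convolutions are computed by im2col
plus one BLAS matrix product per layer; the transposed convolution is the
exact adjoint (verified by an inner-product identity test); batch
normalisation tracks running statistics with momentum 0.1 and eps 1e-5.
Every operation's backward pass is checked against central finite
differences in float64.  The model stack computes in float32.  Being pure
NumPy, forward and backward passes are deterministic on a fixed backend.

## Training recipe

Binary cross-entropy on probabilities (predictions clamped to
[1e-7, 1 - 1e-7] before the logarithms), Adam with framework-default
moments (0.9, 0.999, eps 1e-8), batch size 2, learning rate 1e-4, 30
epochs.  No schedule, no weight decay, no early stopping; the only model
selection is keeping the best-validation-Dice checkpoint alongside the
last.  Shuffling is driven by the run seed, one permutation per epoch, so
identical seeds reproduce identical loss histories.  A non-finite loss
aborts with the epoch and batch index.  Binarisation threshold is 0.5 on
the single-channel probability map (a single logistic output is the
natural reading of a BCE-trained binary segmenter).

## Synthetic phantoms

The phantom generator is the test surface standing in for the private
clinical dataset.  Each subject has a base crescent — the difference of
two offset filled ellipses, rotated to lie roughly horizontal, emulating
the coronal course of the supraspinatus — and 3-5 slices that are mild
shift/scale/angle perturbations of it, so intra-subject correlation exists
and subject-level splitting is genuinely necessary.  Masks are guaranteed
to be a single 4-connected component with area fraction in [0.02, 0.10]
(rejection sampling over geometry parameters).  The area band is a
plumbing default: real-world mask-area statistics for this muscle are not
published, and the band simply keeps targets visible but minoritarian.

Intensities: background 45, target mean per subject ~N(165, 10) clipped to
[145, 190] with a small per-slice drift; `n_distractors` elliptic
structures whose mean lies within `contrast` 8-bit units below the
target's (default contrast 25 — adjacent-muscle similarity); one
distractor always abuts the target boundary to exercise the blurred-
boundary failure mode; additive Gaussian noise (default sigma 8) plus a
smooth background field whose amplitude is tied to the noise level; the
three RGB channels are the same grayscale plane with per-channel offsets
of at most 2 units, emulating a grayscale-to-RGB export.

Two design rules make the generator analysable.  First, geometry and
intensity draw from independent seeded streams, and intensity knobs enter
only arithmetically after all variates are drawn; therefore at a fixed
seed, lowering `contrast` moves distractor pixels monotonically toward the
target intensity and changes nothing else — a fixed global-threshold
segmenter's Dice is provably non-increasing, which is asserted over a
contrast sweep.  Second, in the noiseless maximum-contrast limit the image
is piecewise-constant, so a midpoint threshold recovers the mask exactly
(Dice 100).

What the phantoms do **not** model: coil bias fields, PD fat-suppression
contrast behaviour, anatomy-specific texture, tears or tendon-quality
variation, partial-volume effects, DICOM geometry.  Passing phantom tests
therefore demonstrates that the pipeline, recipe and metrics are correct
and that the architecture can fit separable data — not clinical
performance on real MRI.

## Data handling

Images are 8-bit 512 x 512 x 3 PNGs (grayscale files are channel-
replicated on read); masks are 8-bit {0, 255} PNGs binarised at 128 on
read, which tolerates anti-aliased hand annotations.  Splits shuffle the
subject list with a seeded generator and apportion by largest-remainder
rounding (default 0.70/0.15/0.15; 60 subjects give 42/9/9); all slices of
a subject travel together, and no subject may appear in two splits.
Augmentation is exactly threefold: per input, the original, one rotation
(default 90 degrees — mask-exact without interpolation; arbitrary angles
use nearest-neighbour mask resampling), and one flip whose axis alternates
by sample index so both horizontal and vertical flips occur in any corpus
of two or more images.  The same geometric transform is applied to image
and mask, asserted as an equivariance property.

## Evaluation

Confusion counts are pooled (summed) over all pixels of all evaluated
images and the three formulas applied once to the pooled counts.  Pooled
(micro) aggregation was chosen over per-image macro-averaging because the
published benchmark rows this package audits satisfy
Dice = 2 IoU/(1 + IoU) at printed precision in every row — an identity
guaranteed under shared pooled counts but not under per-image averaging.
Per-image metrics remain available as a secondary output.  Degenerate
cases: a zero denominator returns 0 with a warning; the doubly-empty case
(no foreground in truth or prediction) returns 100.  The bundled
`reported_metrics.csv` transcribes ten published benchmark rows
(five comparison models, five ablation rows); the audit checks the
IoU-Dice identity only — the two published precision figures for the full
model disagree between tables and cannot both come from the same counts,
so no interpretation is attached to them.

## Problem sizes used in the self-checks

The shipped checks run on deliberately small instances chosen to exercise
every contract: phantoms at 64-128 pixels for training checks (the
architecture shape law is additionally verified at the native 512), 40
separable phantoms for the learning-sanity bound (training Dice >= 95 %
within 15 epochs, averaged over three seeds), 20 moderately noisy phantoms
for the loss-descent check, and 1,000 random small masks for the metric
brute-force oracle.  The acceptance script mirrors these sizes and writes
every measured quantity to JSON.

## Known limitations

* CPU-only NumPy backend: training at the native 512-pixel resolution is
  possible but slow; the phantom benchmark runs at 64-128 pixels.
* BatchNorm with batch size 2 uses very small batch statistics, as in the
  original recipe; running statistics make eval-mode prediction stable.
* Channel attention is implemented as squeeze-excitation with an
  average-pool squeeze; variants with a parallel max-pool path exist in
  the literature and are not provided. The reduction ratio is
  configurable.
* The comparative baselines (FCN, SegNet, UNet, DenseNet) are out of
  scope; their published rows are included only for the table audit.
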