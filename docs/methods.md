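# Methods

This note documents the model, the numerical choices, the synthetic data
the package trains and tests on, and the limits of what the bundled
experiments demonstrate.

## Problem setting

Segmenting coronary arteries in 2-D DSA frames is hard for three
reasons: vessel/background contrast is low and backgrounds carry bone
and soft-tissue artifacts; vessel diameter spans more than an order of
magnitude between the trunk (2–3 mm) and terminal branches
(0.2–0.3 mm); and the clinical value of a segmentation depends on
*connectivity* — a topologically broken vessel tree misleads navigation
even when per-pixel overlap is good. The architecture, the loss and the
metrics here each target one of those failure modes.

## Dynamic snake convolution

A snake convolution slides a 1-D kernel (9 taps) along one image axis
while each tap is displaced perpendicular to that axis by a learned
offset. Offsets are produced by a 3×3 convolutional head, squashed by
`tanh` and scaled to `max_step` (default 1 px), then cumulatively summed
outward from the center tap. Consequences:

* the center tap is an exact anchor (offset 0);
* adjacent taps never separate by more than `max_step` pixels, so the
  sampled path is a connected curve — the inductive bias for following
  a continuous vessel;
* the head is zero-initialized, so the layer *starts* as a standard
  axis-aligned convolution and deforms only as training demands. This
  degeneracy is exact (verified to <1e-5 against an independent
  convolution) and stabilizes early training.

Sampling uses bilinear interpolation with pixel centers at integer
(row, column) coordinates, origin top-left. Out-of-image samples clamp
to the border rather than reading zeros: zero padding would inject
artificial dark halos exactly where thin-vessel responses live.

## CFEM

The composite feature-extraction block first builds a tubular feature
map: group-normalize, run x- and y-axis snake convolutions, concatenate
(x first), integrate with a 3×3 convolution + GN + SiLU. The two GN
layers are independent (sharing them is an equally valid reading; the
independent form is strictly more expressive). The dual-path stage then
expands the C-channel tubular map to 4C twice with 1×1 convolutions,
gates one path with the other (`Fexp1 ⊙ GELU(Fexp2)`, a gated linear
unit — the "matrix multiplication" of the design is elementwise, since a
true matrix product is dimensionally undefined here), contracts back to
C, integrates with a depthwise 7×7 convolution, and adds the residual
input. The expansion ratio is a *channel* expansion: a 1×1 kernel cannot
change the receptive field, and the contraction restores the input
width. The dual path consumes the C-channel tubular map rather than the
2C concatenation, which keeps contraction-to-C and the residual
dimensionally clean. All convolutions that feed a normalization layer
are bias-free.

## MCAM

On each skip connection: 1×1 compression to C/4; parallel 1, 3 and 5
kernels (same-padding with edge replication, matching the border
convention used everywhere else); concatenation, GN, 1×1 fusion back to
C/4 (`Fms`). Spatial attention pools `Fms` across channels (mean and
max), stacks the two maps and applies a 7×7 convolution + SiLU +
sigmoid; `Ms` therefore lies strictly in (0,1). Channel attention is
parameter-free: per-channel spatial mean `μ_c` and variance `σ_c²` give
an energy `E_c = (μ_c − t)²/(σ_c² + ε)` and a weight
`M_c = sigmoid(−E_c) ∈ (0, 0.5]` — low energy marks channels whose mean
deviates little from the target `t` relative to their variance.

The energy target `t` is configurable. The default, `global_mean`, uses
the mean of the input over all channels and positions of the sample; a
feature map whose channels are identical then gets the neutral weight
0.5 exactly. The alternative `zero` sets `t = 0`. A per-pixel target is
deliberately not offered: it collapses the energy to
`σ²/(σ²+ε)`, which carries no channel-selective information. The
variance floor is `ε = 1e-4`.

The module output is `Fin + M_c ⊙ Expand1x1(Fs)`: the spatially
weighted C/4 map is restored to C channels, scaled by the channel
weights, and added residually. This is one of several defensible ways to
recombine the two attention branches; it is the minimal one that
preserves the stage's size/channel contract and leaves the skip path an
identity at zero expansion weights.

## Network assembly

Four encoder stages at widths C0·2^i (stem: 3×3 convolution from the
image channels to C0), each a CFEM followed by a stride-2 3×3
convolution that doubles channels; the deepest downsample keeps 8·C0 and
the bottleneck CFEM stays at 8·C0. Decoder stages mirror this with 2×2
stride-2 transposed convolutions, an MCAM on the skip, concatenation,
1×1 reduction to the stage width, and the stage CFEM. The head is a 1×1
convolution to two channels with an elementwise sigmoid; a softmax head
is available behind `NetworkConfig.head`. Output probabilities are
floored to [1e-7, 1−1e-7] so the (0,1) range contract survives float32
saturation. Inputs not divisible by 16 are border-replicate padded and
cropped back (`pad_policy='pad'`), or rejected (`'strict'`).

The base width is configurable; the default 32 yields 13.6 M parameters.
Desk-scale experiments use width 8 (0.9 M parameters).

## Loss

Soft Dice `1 − (2Σpt + s)/(Σp + Σt + s)` with smoothing `s = 1` and
binary focal loss `−mean(α_t (1−p_t)^γ log p_t)` with γ = 2, α = 0.25,
combined with unit weights; all five numbers are knobs
(`LossConfig`). The loss reads the foreground channel of the two-channel
head, with probabilities clamped at 1e-7 before the logarithm.

## Metrics

* Dice / precision / recall from pixel confusion counts; two empty masks
  score 1.0 by convention.
* clDice: skeletons by 2-D morphological thinning;
  `Tprec = |skel(pred)∩gt|/|skel(pred)|`,
  `Tsens = |skel(gt)∩pred|/|skel(gt)|`, harmonic mean. Both masks empty
  → 1, exactly one empty → 0.
* HD95: boundaries are mask pixels with a background 4-neighbor (image
  border counts as background); the two directed nearest-neighbor
  distance sets are pooled and the 95th percentile taken with linear
  interpolation between order statistics. The max-of-directed-percentiles
  dialect is available as `dialect='directed'`. An empty mask returns
  the image diagonal as a documented sentinel.
* Paired comparison of per-image score vectors: mean difference,
  Cohen's d on the paired differences, two-sided paired t-test.
  Zero-variance differences yield p = 1 when the mean difference is 0
  and p = 0 otherwise.

Every metric is cross-checked in the test suite against a brute-force
oracle (all-pairs distances, per-pixel loops, textbook t formulas).

## Synthetic data

The generator emulates the features of DSA that drive the architecture:
a rooted branching tree whose segment widths taper monotonically from a
2–3 mm trunk to 0.2–0.3 mm terminals at 0.08 mm/px (so widths span
~2–37 px at 512×512); bounded random heading changes (tortuosity);
branch splits with probability 0.5 per segment end up to depth 4;
rendering with a radial intensity gradient (darkest at the centerline,
fading toward the wall), a smooth low-frequency background field,
elliptical pseudo-bone blobs, and Gaussian pixel noise. The mask is the
exact union of the stroked tubes, computed before noise; overlapping
branches superimpose as in 2-D projection. For canvases smaller than
512, `scaled_specs` enlarges mm-per-pixel so the anatomy keeps its
proportions. Every sample is a pure function of its seed, and a
manifest of seeds regenerates a dataset bitwise.

What the generator does **not** emulate: cardiac and respiratory motion
blur, contrast-flow dynamics, catheter and guidewire shadows, and
inter-patient anatomy statistics. Passing the bundled experiments
therefore demonstrates that the implementation is correct and trainable,
not that it reaches any particular accuracy on clinical angiograms.

## Augmentation

Three stages, in order: photometric jitter (brightness ±0.2 additive,
contrast ±20%) on the image only; CLAHE on the image only; geometric
transforms applied identically to image and mask — flips (p = 0.5 per
axis), rotation ±15°, affine scale 0.9–1.1 / shear ±8° / translation
±5%, Gaussian blur σ ∈ [0.1, 1.5] on the image — followed by a random
crop (default 256). Masks are warped with nearest-neighbor interpolation
and re-binarized, so labels stay binary; axis-aligned flips and 90°
rotations are implemented as exact array operations. CLAHE uses the
clip-limit convention of `skimage.exposure.equalize_adapthist` (a [0,1]
histogram fraction, default 0.02, 8×8 tiles). Augmentation is applied
online, re-sampled every epoch from the training RNG stream.

## Training loop

Adam (lr 1e-4, weight decay 1e-5, batch 4), constant learning rate by
default with optional cosine decay, early stopping on validation Dice
(strict improvement, patience 20 validation passes), best checkpoint
retained as an `.npz` of named parameters plus a JSON config sidecar. A
single master seed derives (via a seed sequence) the parameter
initialization, batch order and augmentation stream, making runs
bitwise reproducible on one device. A non-finite loss aborts with a
diagnostic rather than training onward. `val_interval` trades
validation cost against checkpoint granularity; `target_val_dice` stops
a run as soon as a requested score is reached (used by the desk-scale
overfit experiment, which by design only needs "≥ 0.85 within 200
steps").

## The autodiff core

No deep-learning framework is part of the dependency set; the network
runs on `snakeseg.nn`, a small reverse-mode autodiff engine over numpy
arrays written for this package. Convolutions lower to BLAS matrix
products (im2col for strided kernels, per-tap accumulation for
same-padding kernels, a fused kernel for deformable sampling +
contraction); the graph is dismantled after each backward pass and an
inference mode skips graph construction entirely. Gradients of every
primitive are verified against central finite differences in the test
suite. float32 is the working precision; float64 inputs are honored
end-to-end (used by the gradient checks).

## Problem sizes in the bundled experiments

The test suite and the acceptance script run entirely on synthetic
data: unit tests use 32–64 px feature maps; shape contracts go up to
256×256 at width 32; the learnability experiment trains a width-8
network on 8 images at 128×128 for at most 200 Adam steps (it typically
reaches Dice 0.85 after ~90 steps and stops there). These sizes were
chosen so a complete run stays in the minutes range on a single CPU
while still exercising every code path at realistic anatomy
proportions.

## Known limitations

* The printed parameter count of the original architecture cannot be
  reproduced exactly because its base width is not public; width 32
  (13.6 M parameters) is the closest standard choice.
* CPU-only numpy training is ~2 orders of magnitude slower than a GPU
  framework; the package is built for understanding and verification at
  desk scale, not for full-dataset training.
* The recombination of spatial and channel attention in MCAM and the
  energy target `t` are documented package choices among several
  defensible readings; both are exposed as configuration.
* clDice is implemented as a metric only, not as a differentiable loss.
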