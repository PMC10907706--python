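# Methods

## Problem and model

Oral CBCT tooth segmentation is a binary (tooth / background) dense
prediction task on axial slices of resampled CBCT volumes. The failure modes
this package targets are structural: contour blur makes the tooth/bone
boundary ambiguous, and the crown-to-root scale imbalance makes roots a
small minority of foreground pixels. The design responds in two places — the
architecture (feature capture and multi-scale fusion) and the objective
(a hard-sample-weighted loss).

DSFNet is a depth-3 U-shaped network. Encoder stages are two CBG
(Conv3×3–BatchNorm–GELU) blocks each, with 2×2 max-pool downsampling and a
channel schedule (C0, 2C0, 4C0) plus an 8C0 bottleneck; decoder stages
mirror this with kernel-2 stride-2 transposed convolutions and skip
concatenation. C0 defaults to 32 and is configurable (the reference design
never fixes widths, so they are a free parameter here).

### FCM

Each skip connection passes through a Feature Capture Module. The input is
compressed to C/4 channels by a 1×1 convolution; a CBG branch captures local
structure while a transformer branch captures long-range structure; the
branch sum is expanded back to C channels by a 1×1 convolution and added to
the unmodified input. Choices the design left open, fixed here:

- The attention operates on the compressed C/4 feature map (the cheaper of
  the two readings of "compressed feature maps in the bottleneck").
- Tokenization: non-overlapping patches on a fixed `token_grid` (default
  14 per side, so N = 196 tokens at every skip level regardless of
  resolution — attention cost is bounded identically everywhere). Linear
  patch embedding to dimension C/4, a learnable positional encoding, one
  pre-norm MSA residual and one pre-norm MLP residual (exactly one of each),
  then a linear un-projection back to the spatial layout. Heads default to
  4, MLP ratio to 4.
- The expanding 1×1 convolution is zero-initialized, so an untrained FCM is
  the identity map — skips start safe and the module grows into the
  residual. This is asserted by test.

### MFFM

Four scales feed the fusion module: the bottleneck output and the three
decoder outputs (the decoder side carries segmentation-ready semantics and
is exactly four scales deep). Each is 1×1-projected to C0 and bilinearly
resized to full resolution. Pathway 1 applies CBAM per scale (channel
attention: shared two-layer MLP over spatial-average and spatial-max pooled
vectors, sigmoid; spatial attention: 7×7 convolution over channel-average
and channel-max maps, sigmoid). Pathway 2 computes the inter-scale map
`[A_1..A_4] = σ(conv7×7(concat(F_1..F_4)))` with exactly 4 output channels,
one broadcast weight per scale. The sigmoid on A_i is a deliberate choice
(the formula in the source design shows none) so that all attention weights
are bounded in [0, 1] like the CBAM maps. Output: `CBG(F_c) + F_c` on the
4·C0-channel concatenation of the gated scales. CBAM reduction ratio is 16
for C ≥ 64, else 4 (the customary default).

The head is a 1×1 convolution to one channel plus a sigmoid; masks are
thresholded at 0.5. With `use_mffm` off the head consumes the last decoder
output; with `use_fcm` off skips are identity — the two flags and the loss
configuration reconstruct all ablation variants from configuration alone.

## Loss

The mixed objective is `α·L_D* + (1−α)·L_F` (defaults α = 0.5, γ = 2,
γ′ = 1, ε = 1e−6; this parameterization was the best-performing row of the
source ablation). The improved Dice Loss is

    L_D*(t) = 1 − (2^(1+γ′)·t + ε) / ((t+1)^(1+γ′) + ε)

**Aggregation.** The scalar formula is defined per sample; summing raw
intersections over an image would make the denominator `(Σŷy + Σy)^(1+γ′)`
explode with image size. We therefore aggregate through the foreground mean
`t = Σ(ŷ⊙y)/Σy`, which keeps t on the unit scale of the scalar analysis,
reproduces the scalar worked examples exactly, and reduces to a standard
soft-Dice-style loss at γ′ = 0. Note the denominator of the underlying Dice
form is `ŷ·y + y`, not the conventional `ŷ + y`; it is implemented literally
(the published worked examples confirm this form), which means false
positives influence this term only through the focal component.

**Degenerate inputs.** If a batch has no foreground (Σy = 0) we set t = 1,
so the Dice term is exactly 0 and background-only crops contribute only
focal loss. Predictions are clamped to [1e−7, 1−1e−7] before logs and
powers, keeping every loss finite at saturated outputs. Worked-example
checks use ε = 0 because the printed arithmetic ignores smoothing; training
uses ε = 1e−6. Focal loss reduces by the mean over all pixels and carries no
class-balancing weight.

## Metrics

DSC is `2|P∩T|/(|P|+|T|)` (1.0 when both masks are empty). Surfaces are
foreground voxels with a face-adjacent background neighbour (6-connectivity
in 3-D; array borders count as background). ASSD is the *pooled* mean over
the union of both directed nearest-surface distance sets — the common
medical-imaging convention; it differs from the mean-of-two-means variant
when the two surfaces have different sizes. Distances honour voxel spacing
via a Euclidean distance transform and are reported in mm; the
implementation is verified against a brute-force all-pairs oracle. ASSD is
undefined (an error, surfaced per volume in evaluation reports) when either
mask is empty. Evaluation restacks per-slice predictions into the 3-D
volume and computes both metrics in 3-D, since boundary distance in mm is a
volume-level quantity.

## Preprocessing

Volumes are resampled to isotropic 0.4 mm (trilinear for intensities,
nearest-neighbour for labels), clipped to [0, 2500] to suppress
metal-artifact extremes, divided by 2500 (fixed global scale, not
per-volume min–max), and instance labels are collapsed to binary. Axial
slices are center-cropped / symmetrically zero-padded to 224×224 with
geometry metadata retained so predictions can be restacked losslessly for
in-plane sizes ≤ 224. The 6:2:2 split is a seeded shuffle with
floor/floor/remainder sizing (98 volumes → 58/19/21).

## Synthetic phantoms

The generator emulates the two stated difficulty mechanisms, not clinical
anatomy: an arch of bright elliptical crowns (2200 intensity units) with
thin tapering roots (1500) over a smooth bone band (900) and background
(100); the ground truth is the pre-blur geometry; the image is Gaussian-blurred
(σ = 1.5 px), noised (σ = 40 units) and occasionally crossed by a bright
streak (metal-artifact stand-in, 30% of slices). Root widths are forced
below crown radii by a constructor invariant. Defaults were chosen once so
that the default 224-px slice has a foreground fraction of roughly 5% and
every root component is smaller than every crown component; both are
asserted statistically over 100 slices.

What a green phantom test does *not* establish: performance on real CBCT.
Phantoms lack true CT noise texture, partial-volume effects, anatomical
root/crown shape variation, neighbouring-teeth contact and real metal
artifacts. They establish that the pipeline is wired correctly and that the
architectural/loss mechanisms behave in the intended direction.

## Training

AdamW (decoupled weight decay 0.05 applied to rank ≥ 2 parameters only),
initial learning rate 3e−4, per-epoch cosine decay
`lr(e) = lr0·½(1+cos(πe/(E−1)))` (per-epoch rather than per-iteration — the
protocol's granularity is unstated), 50 epochs and 224×224 inputs at full
scale. Validation runs after every epoch; the checkpoint with the best
validation DSC is kept (the selection criterion is unstated in the source
protocol; DSC is the headline metric). Batch default is 8 — single-CPU desk
scale rather than the original four-GPU batch of 128. No data augmentation.
Checkpoints embed the full configuration, so `eval`/`predict` are
self-describing. Global seeding (parameter init and batch shuffling) makes
runs bit-reproducible on the same machine.

**Desk-scale acceptance study.** The spirit of the full-scale experiment is
checked on 5 phantom volumes (32×32×10) with C0 = 8, token grid 4, heads 2,
10 epochs, batch 4, lr 3e−4, 3 seeds: held-out DSC must exceed 0.80 for the
full model with mixed loss, the full model must not trail the plain
baseline, and the mixed loss must not trail plain Dice. These thresholds
were fixed before measurement; the measured study (seeds 0–2) gave
full+mixed 0.938, full+dice 0.850, baseline 0.806 mean DSC.

## Numerical choices

- float32 forward/backward for speed; losses on plain arrays are computed
  in float64 so scalar worked examples are exact to print precision.
- Batch norm uses biased batch variance and momentum 0.1 running statistics;
  evaluation mode uses running statistics and is bit-deterministic.
- Bilinear resizing uses the half-pixel-center convention via explicit
  separable interpolation matrices (exactly transposed in the backward pass).
- Max-pool ties route the gradient to a single argmax element.
- Weight init: truncated normal (std 0.02) for attention/MLP weights,
  fan-in uniform for convolutions, zeros for the FCM expansion.

## Known limitations

- Single-layer attention per skip; no windowed attention — cost is bounded
  by the fixed token grid instead.
- The NumPy engine is single-process and eager; wall-clock scale is desk
  experiments, not the full 50-epoch clinical protocol.
- ASSD on very coarse masks inherits distance-transform discretization at
  the voxel level (exact for surface-voxel-to-surface-voxel distances).
- 2-D slice model; no 3-D convolutions or per-tooth instance separation.
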