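# Methods

`lungattn` implements an attention-augmented U-Net for lung-field
segmentation in chest radiographs, together with a synthetic phantom
generator so the whole pipeline can be exercised and validated without
any clinical data. This note records the model, the main parameter
choices, the scope of the phantom generator, the numerical decisions,
and the limitations.

## Attention blocks

Both attention variants fuse a channel descriptor with a spatial map and
gate the feature map residually.

**Channel attention.** For a feature map `F ∈ R^{C×H×W}` the channel
branch is a squeeze-and-excitation bottleneck:

```
F_channel = ReLU(BN(W1 · ReLU(W0 · GAP(F))))
```

`GAP` is global average pooling, `W0 : C → h` and `W1 : h → C` with
hidden width `h = max(1, round(r·C))` and reduction ratio `r = 0.5`.
The output is one non-negative weight per channel.

**Spatial attention.** A three-scale pyramid with exactly five 3×3
convolutions: two stride-2 contracting convolutions (H → H/2 → H/4),
one convolution at the coarsest scale, then two expanding convolutions
interleaved with fixed ×2 upsampling (bilinear by default, nearest
selectable), with lateral additions from the contracting path and a
final additive skip from the input. The output `F_spatial` has the same
shape as the input.

**X attention (same-level fusion).**

```
M_X = σ(F_spatial(F) ⊗ F_channel(F))
```

where `⊗` broadcasts the per-channel weights over space and `σ` is the
logistic sigmoid, so `M_X ∈ (0,1)` elementwise.

**Y attention (cross-level fusion).** The spatial branch reads the
shallow feature map `F` (the skip connection) while the channel branch
reads a deeper feature map `F_d ∈ R^{C_d×H'×W'}`; the MLP adapts
`C_d → C` so the fused map matches the shallow shape:

```
M_Y = σ(F_spatial(F) ⊗ F'_channel(F_d))
```

**Residual refinement.** Both variants gate via

```
F_out = M ⊗ F + F
```

so for non-negative features the output is bounded in `[F, 2F]` and the
block can never suppress a feature below its input — attention is purely
additive emphasis.

## Network

A U-Net whose encoder is a stem convolution followed by four residual
stages (each halving resolution) and a bottleneck; input sides must be
divisible by 32. X modules attach after encoder stages (position 1 =
shallowest); Y modules sit on the decoder, taking the (possibly
X-refined) skip as the shallow input and the next-deeper decoder feature
as the deep input, so X and Y chain when placed at the same position.
Decoding uses 2×2 stride-2 transposed convolutions, concatenation with
the skip, and double-convolution blocks; a 1×1 convolution plus sigmoid
produces a per-pixel lung probability. Placements are named with labels
such as `X(1)+X(2)+Y(1)+Y(2)`; `baseline` has no attention.

Encoder presets: `tiny` (widths 8/16/32/64, one block per stage, used
throughout the tests and examples), `small`, and `resnet101`
(3/4/23/3 blocks at widths 256/512/1024/2048, provided for parameter
accounting — `count_learnable_parameters` computes its size analytically
without instantiating it). A Y block at 256/512 channels adds about
3.1 M parameters, under 1 % of the full backbone.

## Training regimen

SGD with momentum 0.9, batch size 4, initial learning rate 0.01, MSE
loss between the sigmoid output and the binary mask, at most 10,000
iterations. The learning rate is divided by 10 when validation Dice
fails to improve strictly for `plateau_patience` (default 5) consecutive
evaluations; training stops early after `early_stop_patience` (default
15) evaluations without improvement — this counter is not reset by
decays. Validation Dice is evaluated every 50 iterations and the best
weights are restored at the end. No data augmentation is used, and the
configuration refuses to enable it.

One deviation from zero-initialised biases: the hidden-layer bias of the
channel MLP is initialised to +0.1. With zero biases every hidden ReLU
unit starts dead, the channel vector is exactly zero, the fused map is
constantly 0.5 and no gradient ever reaches the attention block; the
small positive bias keeps the gate alive at initialisation.

## Pre- and post-processing, metrics

Images are resized bilinearly to the network size and
histogram-equalised with a 256-bin CDF lookup table
(`lut = (cdf·255) // N`; a constant image maps to 255); no further
normalisation. Predictions are thresholded strictly at `p > 0.5` and
only the two largest 8-connected components are kept, matching the
two-lung prior.

Metrics come straight from the confusion counts: Dice
`2TP/((TP+FP)+(TP+FN))`, sensitivity `TP/(TP+FN)`, PPV `TP/(TP+FP)`.
Conventions: if TP=FP=FN=0 (both masks empty) all three are 1; a metric
whose own denominator is 0 is 0. Dice is algebraically the harmonic mean
of sensitivity and PPV, which the tests verify exactly. Cross-validated
results are macro-averaged per image, then aggregated across folds as
mean ± sample standard deviation (ddof = 1; a single fold reports 0) and
formatted to three decimals.

## Phantom generator

Each 64×64 phantom contains two star-convex "lung" lobes (ellipses with
a low-order sinusoidal boundary wobble), rendered dark (intensity 85) on
brighter tissue (175), smoothed with a Gaussian (σ = 1), overlaid with a
sinusoidal rib pattern (contrast 12) and Gaussian noise (σ = 6).
Rejection sampling guarantees every phantom has exactly two 8-connected
components separated by the midline, each lobe covering 8–22 % of the
frame and the pair 15–45 % in total. The generator is deterministic per
seed; dataset seeds derive as `(base_seed·1_000_003 + i) mod 2^31`.

These phantoms test the *machinery* — shapes, plumbing, optimisation,
metrics — not clinical performance. They lack mediastinal structure,
clavicles, costophrenic-angle geometry, pathology, and scanner
variation; numbers obtained on them do not transfer to radiographs.

## Data protocol

Images are shuffled once per seed and partitioned into five disjoint
test folds covering every image (~20 % each); within each fold the
remainder is split 70/10 (of the total) into train/validation by largest
remainder, so 100 images give exactly 70/10/20.

## Numerical implementation

The network runs on a small reverse-mode autodiff engine written on
NumPy (no deep-learning framework dependency): convolution via im2col
(`sliding_window_view` + BLAS matmul) with a col2im backward, 2×2
stride-2 transposed convolution, batch normalisation (batch statistics
when the batch has more than one element, running statistics otherwise
and in eval mode), fixed ×2 upsampling expressed as separable
interpolation matrices with exact adjoint backward. All gradients are
verified against central finite differences in the test suite. Training
at the tiny preset runs at roughly 0.15 s per iteration on one CPU
thread; the problem sizes in the examples (64×64 images, 8–20 phantoms,
100–300 iterations) are chosen so every workflow finishes in minutes.

## Limitations

- Phantoms are far simpler than radiographs (see above); reported Dice
  values characterise the implementation, not clinical accuracy.
- The `resnet101` preset is supported analytically but is impractical to
  train in this CPU-only implementation.
- MSE on sigmoid outputs follows the original regimen; Dice or
  cross-entropy losses typically converge faster but are out of scope.
- Batch normalisation falls back to running statistics for
  single-element batches, which slightly changes the training dynamics
  of a final odd batch.
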