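# Methods

## Problem and approach

Volumetric segmentation networks spend most of their inference cost in the
residual encoder, but residual blocks behave like an ensemble of paths with
weak mutual dependence: for a given input, many blocks are dispensable. This
package learns an *image-specific* inference path for a trained, frozen 3D
segmentation network. A separate policy network maps the input volume to one
Bernoulli keep-probability per residual block; sampled (training) or
thresholded (deployment) actions gate the blocks, and the policy is optimized
by policy gradient to maximize a reward that trades block usage against
voxel-level correctness.

## Gated backbone

A DeepLab-V3-style 3D network: conv stem (3×3×3, in-plane stride 2) →
residual stages → ASPP → convolutional decoder.

- **Gateable set.** Exactly the residual blocks; stem, ASPP and decoder
  always run. A dropped block emits its shortcut branch: identity for
  same-shape blocks, the existing strided 1×1×1 projection for blocks that
  change resolution or width. This keeps tensor shapes valid for *every*
  action pattern, including dropping the first, dimension-changing blocks.
  Dropped blocks are skipped, not zero-multiplied, so their batch-norm
  statistics are never touched by gated passes.
- **Variants.** `resnet18-style` = 4 stages × 2 basic blocks (8 gateable
  blocks); `resnet50-style` = (3,4,6,3) bottleneck blocks (16); `tiny-k` = k
  basic blocks for CPU-scale experiments. Default stage widths are compact
  (16/32/64/128; ×4 bottleneck expansion) and configurable — the block
  *count* is the structural property of each variant, the widths are not.
- **Anisotropy.** Every convolution stride along z is 1, so volumes are never
  downsampled along the slice axis; total in-plane stride is 8 (stem 2,
  two strided stages; the last ResNet stage uses dilation 2 instead of
  stride, the usual atrous trick at output stride 8). Inputs whose in-plane
  dims are not multiples of 8 are zero-padded and the output cropped back.
- **Stem/ASPP choices** (unspecified upstream, chosen here): 3×3×3 stem
  without pooling; ASPP with a 1×1×1 branch, 3×3×3 branches at in-plane
  dilation rates (1, 2, 4) and a global-image-pooling branch — small rates
  suit the small feature maps of desk-scale volumes. Decoder: ×2 trilinear
  upsampling, two 3×3×3 convs, 1×1×1 two-class classifier, trilinear
  upsampling of logits to input resolution, softmax.
- `num_classes` is fixed at 2 (binary foreground task). Argmax ties at
  (0.5, 0.5) go to background.

## Policy network and policy math

A 3D CNN much cheaper than the backbone it gates (otherwise gating saves
nothing): optional ×2 in-plane average-pool of the input, four
conv(3×3×3, in-plane stride 2)/BN/ReLU stages with widths (8, 16, 32, 32),
global average pooling, one linear layer to N logits, sigmoid. It shares no
weights with the segmentation network.

The distribution over actions is the independent Bernoulli product
π(a|x) = ∏ p_n^{a_n}(1−p_n)^{1−a_n}; p_n is the probability of **keeping**
block n (the algebra fixes this reading: P(a_n=1) = p_n and a_n = 0 means
drop). Log-probabilities are computed as Σ log(p_n a_n + (1−p_n)(1−a_n)) with
p clamped to [1e−6, 1−1e−6]. Test-time decision rule: threshold at 0.5
(keep iff p_n ≥ 0.5), deterministic; sampling remains available.

## Reward

Per voxel i: `1 − (|a|₀/N)²` when VDC(i) = 1, else `−τ`, where
VDC(i) = (2(y′_i∧y_i)+1)/(y′_i+y_i+1) ∈ {1, 0.5} for binary masks. The
squared usage term rewards dropping progressively more strongly as usage
falls. τ (default 50) sets how many correct-voxel usage rewards one wrong
voxel cancels; large τ forces conservative (keep-everything) policies.
Voxel rewards are **averaged** (not summed) into the scalar R(a) so τ keeps
the same meaning across volume and patch sizes; the aggregation rule is a
package choice, as is the mean (over batch) convention.

## Training

- **Pretraining** of the backbone: voxel cross-entropy + soft Dice, equally
  weighted — the standard pairing for class-imbalanced binary 3D
  segmentation. Adam, lr 0.01, ×0.1 decay every 100 epochs, up to 400 epochs
  (reference defaults; desk-scale runs use far fewer epochs, see below).
- **Policy training** (REINFORCE): for each volume the policy emits p, one
  action vector per Monte-Carlo sample (default 1, classic single-sample
  REINFORCE) is drawn on the learnable blocks, the gated frozen backbone
  predicts, and the loss −R(a)·Σ_learnable log π contributes gradient
  −R(a)(a_n − p_n) per logit. Adam, lr 0.001 by default. No reward baseline
  by default (an exponential-moving-average baseline is available behind
  `use_baseline`, off for fidelity to the plain estimator).
- **Curriculum**: epoch c (1-based, clipped at N) learns only the last c
  blocks; earlier blocks are forced to keep and excluded from the
  log-probability sum, so their logits provably receive zero gradient.
- **Freezing**: the segmentation network runs in eval mode during policy
  training and its weights (including batch-norm buffers) are asserted
  bit-identical before and after.
- Whole small volumes are batched without patch sampling at desk scale;
  large NIfTI inputs are expected to be cropped by the caller.

## Synthetic phantoms

`data_io` generates volumes (default 16×64×64, in-plane divisible by the
stride 8) with 1–2 ellipsoid or blob foreground objects (radii ~U(4, 12)
voxels, capped per axis so objects fit), foreground/background intensities
1/0, additive Gaussian noise (sd 0.2), and a per-image `difficulty` ∈ [0, 1]
that removes up to 70% of the contrast and roughens blob boundaries (smooth
Gaussian random field added to the implicit surface). Datasets sample
difficulty from U(0, 0.5) by default, giving easy and hard cases in one
dataset. Splits are 70/15/15, deterministic in the seed; generation uses
NumPy's PCG64 generator, so (spec, seed) reproduces volumes bit-identically.

The phantoms emulate a learnable binary segmentation task with per-image
difficulty variation. They do **not** emulate CT physics (no bias fields,
partial-volume effects, anatomy-correlated backgrounds, or multi-organ
context), so passing tests demonstrate the mechanics and optimization
behavior of the method, not clinical-grade liver segmentation. The real-data
path reads NIfTI volumes (RAS-reoriented, optional clip to [−200, 250] HU
then min-max to [0, 1]); full-scale CT training is out of scope here.

## Desk-scale experiment sizes

Chosen so the whole suite runs comfortably on one CPU:

- Backbone smoke benchmark: `tiny-4`, 40 phantoms (28 train), 30 epochs →
  held-out Dice ≥ 0.8.
- Redundancy recovery: `tiny-6` pretrained with blocks 5–6 (indices 4, 5)
  built as frozen, verified no-ops (final batch-norm scale and shift zeroed,
  branch excluded from optimization — the branch output is identically zero
  in both modes). Policy: 30 epochs, lr 0.01. The higher-than-default policy
  lr is the desk-scale setting: with ~30 short epochs the default 0.001
  cannot move logits far enough from initialization to saturate the keep
  probabilities; the reference lr applies to the much longer full-scale
  schedule.
- Penalty-dominated limit: `tiny-2` (both blocks carry accuracy), τ = 10⁶ —
  the learned policy keeps everything. Note this limit requires every block
  to matter: in a trained network with genuinely redundant blocks, dropping
  them changes no prediction, so even an enormous τ rightly does not force
  them on.
- Difficulty knob: `tiny-2` on 8×32×32 blobs, 8 epochs, 3 seeds per
  difficulty ∈ {0, 0.5, 1}: mean achievable Dice is non-increasing.

## Numerical choices

- All network arithmetic in float32; policy math, losses and rewards in
  float64. Probabilities clamped at 1e−6 before logs.
- Conv3d via im2col + GEMM with symmetric "same" padding ((k−1)·dilation)/2;
  trilinear upsampling as separable half-pixel linear interpolation matrices
  (backward = exact adjoint).
- Batch norm uses batch statistics in training and running statistics
  (momentum 0.1, unbiased variance) in eval.
- All-keep gating takes the same code path as the ungated forward, so the
  two are bit-identical, and the analytic MAC counter is non-increasing
  along any chain of additional drops (it need not be monotone across
  unrelated action sets of equal size, since blocks differ in cost).
- Equal-dropping comparisons round the learned policy's fractional mean
  dropped count half-up to pick the heuristic n.

## Known limitations

- Single-sample REINFORCE without a baseline is high-variance; desk-scale
  tasks converge anyway, large-scale use would likely want `use_baseline`
  or more `mc_samples`.
- Binary segmentation only; one gating decision per block (no per-stage or
  per-voxel gating); backbone and policy are trained separately, never
  jointly.
- The NumPy toolkit is single-threaded BLAS-bound; it is meant for
  CPU-scale experiments, not full-resolution CT training.
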