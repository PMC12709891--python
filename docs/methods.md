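# Methods

## Problem setting

Individual-tree segmentation from UAV-LiDAR plantation scans is usually a
two-step process: a graph-based coarse isolation tool cuts the plot cloud
into per-tree samples, and a semantic-segmentation network then cleans each
sample, separating the target tree (label 1) from everything the coarse step
could not remove — retained ground points and crown fragments of overlapping
neighbours (label 0). This package implements the second step end to end:
the network, its learning-rate search, evaluation metrics, structural
parameter extraction, and a synthetic generator that reproduces the input
regime so the whole pipeline is testable on one CPU without field data.

## Data model and preprocessing

Clouds are plain-text `x y z [nx ny nz] [label]` files. Normals, when used,
are per-point PCA normals: the smallest-eigenvalue eigenvector of the k-NN
covariance, sign-fixed to positive z (ties positive x, then y) since
orientation is not used downstream.

All network processing happens on coordinates normalised to centroid zero
and maximum axis extent 1. The grid sizes of the architecture
(0.01/0.025/0.1/0.25 by default) are sub-meter fractions that are only
meaningful on normalised coordinates; the transform is recorded and exactly
invertible. Grid cells are half-open axis-aligned cubes anchored at the
minimum corner, so cell membership is deterministic and invariant to point
order; voxel ids are assigned in lexicographic cell order.

The train/test split permutes sample ids under a seed and rounds the train
count to the nearest integer (ties toward train), which maps 600 samples at
4:1 to exactly 480/120.

## Network

The model is an encoder–decoder over sparse voxels:

1. **Patch embedding.** The cloud is voxelised at the finest grid; each
   occupied cell contributes the mean offset of its members from the cell
   center, the mean normals (if used), and the cell's mean coordinates,
   linearly embedded and layer-normalised. Feeding the absolute (normalised)
   cell position at embedding follows the convention of point transformers;
   within-cell offsets alone carry no information about where a cell sits
   relative to the trunk axis or the ground, which is exactly what
   distinguishes the two classes here. Aggregation uses a canonical
   (voxel-id, xyz) summation order so the embedding is bitwise identical
   under any permutation of the input points.

2. **SGTramba blocks** (grouped attention + state-space sequence layers).
   Farthest-point sampling — seeded at the lexicographically smallest point
   so results are order-independent — picks G group centers; each group is
   the center's k nearest neighbours. Within a group, multi-head attention
   uses scaled per-head dot-product logits, and values are elementwise
   modulated by a two-layer perceptron over the relative displacement
   concatenated with its sine/cosine encoding at dyadic frequencies
   2^i, i < L. This realisation folds the "frequency-domain" enhancement
   entirely into the positional pathway; there is no separate FFT filter.
   Group features (member-wise max) receive a learned non-negative
   importance score ReLU(BN(f W)); groups are sorted by score in descending
   and ascending order, each ordering is processed by a shared-weight stack
   of M gated selective state-space layers (causal depthwise convolution,
   softplus step sizes, diagonal negative-real state matrix so every
   discretised pole lies in (0,1)), and the two passes are averaged after
   inverse permutation. Per-point outputs are attention outputs plus the
   post-sequence group feature broadcast to members (averaged for points in
   several groups; points missed by every group receive their nearest
   center's group feature); a final projection enters through a residual
   connection, so a zero-initialised block is exactly the identity.

3. **WGrid pooling.** Before each stage's pooling, the N x c feature matrix
   is treated as an image and passed through a one-level 2-D Haar transform;
   the three detail subbands are scaled by an enhancement factor alpha
   (default 2.0 — amplify fine structure) and the reconstruction is added
   back. Rows are in voxel order, giving the matrix spatial coherence. The
   training path uses a hand-differentiated Haar implementation that matches
   PyWavelets exactly (verified in tests); the standalone operation supports
   any discrete wavelet via PyWavelets. Features are then linearly projected
   and max-pooled per cell while coordinates are mean-pooled; the
   cell-membership map is cached for the decoder.

4. **MSFF fusion.** The previous stage's fusion output is aligned to the
   current resolution by nearest neighbour, concatenated with the current
   features, fused by a pointwise convolution + batch norm + ReLU, gated
   channel-wise by sigmoid(ReLU(F_t)) (the literal gate; a flag drops the
   inner ReLU, which otherwise confines the gate to [0.5, 1)), and refined
   by a spatial branch aggregating the k_s = 9 nearest neighbours — the
   point-cloud analogue of a 3x3 stencil — with its own sigmoid gate, added
   residually. Inside the network the fused feature enters through a
   zero-initialisable projection with a skip connection.

5. **Decoder and head.** Stages are reversed by mapping de-pooling (each
   member point receives its cell's feature), concatenation with the cached
   skip features and a linear reduction; a layer-normalised linear head
   outputs per-point softmax probabilities. Per-stage layer normalisation
   keeps the residual/wavelet amplification bounded.

Ablation switches reproduce an 8-arm design from config flags alone:
`use_sgtramba=False` degrades blocks to plain grouped attention (no Fourier
pathway, no sequence layers), `use_wgms=False` disables the wavelet
enhancement and makes fusion a pass-through, and the optimizer search is a
training flag.

## Learning-rate search (SCPO)

A box-bounded hybrid of sinh/cosh bounded moves and particle-swarm exchange.
Iteration t applies one SCHO-style move — exploration for
t <= phase_switch * T (default 0.5): X <- X_best -/+ r1 W1 X with
W1 = r3 a1 (cosh r4 + u sinh r4 - 1), a1 = -3.9 t/T + 3m, u = 0.388;
exploitation afterwards: X <- X + r11 (sinh r11 / cosh r12) W2 (X_best - X)
with W2 = r6 a2 and a2 = 2 t/T, a linear choice for the required
"increasing with iteration" behaviour — then evaluates, then applies a PSO
velocity/position update from personal and global bests and evaluates again.
Bounds are enforced by clamping; failed objective evaluations count as +inf.
The printed velocity rule carries no inertia term, so w defaults to 0 inside
the hybrid; as a *standalone* baseline that choice degenerates into a greedy
contraction, so comparisons against "pure PSO" use the canonical
inertia-weighted coefficients (w = 0.729, c1 = c2 = 1.49445).

For the learning rate the search runs in log10 space over [1e-8, 1e-5]
(the bounds span three decades) with a short training run as the probe and
validation loss as fitness; probe length (3 epochs) and swarm size are
configurable.

## Training

Per-point cross-entropy, Adam, batch accumulation over 4 clouds, 200 epochs
by default. Everything is seeded: initialisation, shuffling, the search.
The implementation runs on a small hand-written reverse-mode autodiff engine
over numpy arrays (`tmwsnet.autodiff`), sized for the problem: gradients are
validated against central finite differences, and the selective-scan output
against an explicit step-by-step recurrence.

## Metrics

One-vs-rest confusion counts per class give mIoU and macro precision/recall/
F1. The accuracy reported as `macc` is overall accuracy (correct points over
all points), matching how the quantity is defined in the segmentation
literature this package follows; macro per-class accuracy is additionally
reported as `macc_macro`. F1 uses the 1/N macro mean so it lies in [0, 100]
(the raw class sum is available behind a flag), and is 0 for a class with
zero precision and recall. Classes with empty denominators are excluded from
macro means and logged, never silently zeroed. R^2 = 1 - SS_res/SS_tot
evaluates continuous predictions.

## Structural parameters

* **Height**: 99.9th percentile of tree-point z minus the 1st percentile of
  all z as a ground proxy (robust to isolated low outliers). The percentile
  estimator under-reads the true tip by about 1% at typical densities —
  within the 2% band it is designed for.
* **DBH**: tree points in the 1.2–1.4 m slice above ground, algebraic
  (Kasa) circle fit plus one Gauss–Newton refinement, needing at least 5
  slice points.
* **Crown diameter**: mean of the x- and y-extents of tree points above
  half the tree height.

## Synthetic generator

Each sample is one target tree — a cylinder trunk (lateral surface, 1:4
trunk:crown point ratio) under a filled ellipsoid crown — plus a rough
ground patch (Gaussian z, sd 5 cm over an 8 m square) and an upper-hemisphere
fragment of a neighbour crown displaced horizontally, mimicking the
over-segmentation artifacts of the coarse isolation step. The crown is
filled, not a shell, because LiDAR returns penetrate canopies; combined with
the neighbour fragment this makes the classes non-separable by height alone.
Default morphology ranges (trunk height 4–7 m, trunk radius 10–20 cm, crown
semi-axes 1.6–2.8 m horizontally and 2.0–3.5 m vertically, lean up to 5°)
represent mature plantation trees. Default sample sizes are 4000 tree /
1200 ground / 800 neighbour points; the network experiments use 2000/600/400
(~3000 points per sample), a deliberate scale-down that keeps every
experiment reproducible on one CPU core in minutes.

What the generator does **not** model: beam geometry and occlusion, foliage
clumping, multi-stem or bifurcated trunks, understory vegetation, and
species-specific allometry. Passing tests therefore demonstrate that the
implementation is correct and that the architecture can learn this class
structure; they do not certify field accuracy on real plantation scans.

## Numerical and design choices

* Half-open voxel intervals, lowest-index tie-breaks in FPS/k-NN sorting,
  stable sorts for score ordering: every discrete choice is deterministic
  and permutation-invariant.
* Degenerate inputs: single-point clouds normalise with scale 1 (warning);
  a single group degrades attention to a singleton softmax; G = 1 batches
  use stored batch-norm statistics.
* The experiments behind the shipped defaults use a reduced configuration —
  channels (24, 24, 24, 24), one block per stage, G = 24, k = 12, L = 2,
  M = 1, state dim 8, 70 epochs at a constant 3e-3 learning rate — the
  smallest model we found that both cleanly overfits one sample and
  generalises robustly across plots at the generator's default conditions
  (~3000-point samples, 20 train / 5 test). Width mattered most: halving
  channels to 16 costs roughly 4-6 points of held-out mIoU. PCA-normal
  input features did not help at this scale and stay off by default.

## Known limitations

* The wavelet enhancement's training path supports the (default) Haar
  wavelet; other discrete wavelets are available in the standalone operation
  but not differentiated.
* The importance score influences only the ordering, which is
  non-differentiable, so its weights keep their initial values; this is
  inherent to score-based reordering.
* Checkpoints store weights plus config but not optimizer state; training
  cannot be resumed mid-run.
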