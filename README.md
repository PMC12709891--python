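# tmwsnet

Semantic segmentation of individual trees from coarse-segmented UAV-LiDAR
point clouds, plus the structural parameters foresters actually want from
the result: tree height, diameter at breast height (DBH) and crown diameter.

Plantation scans are first cut into per-tree samples by a graph-based
isolation tool; those samples are imperfect — they retain ground points and
drag in crown fragments of overlapping neighbours. This package provides
the refinement step: a point-cloud segmentation network that labels each
point of a sample as *tree* (1) or *other* (0), together with everything
needed to develop and evaluate it on one CPU:

* **TM-WSNet**, an encoder–decoder over sparse voxel grids whose stages
  combine three components: **SGTramba** blocks (grouped multi-head
  attention with a Fourier-encoded relative-position pathway inside each
  point group, and bidirectionally importance-ordered selective state-space
  (Mamba-style) layers across groups), **WGrid** pooling (a one-level 2-D
  discrete wavelet transform of the feature matrix with detail subbands
  amplified by a factor α before grid max-pooling), and **MSFF**
  (channel- and spatially-gated multi-scale feature fusion across stages).
* **SCPO**, a bounded stochastic optimizer hybridising sinh/cosh-bounded
  moves with particle-swarm information exchange, used to search the initial
  learning rate in log10 space over [1e-8, 1e-5].
* Metrics (mIoU, accuracy, macro precision/recall/F1, R²) with brute-force
  oracles, and structural-parameter extractors (percentile height,
  least-squares circle DBH, crown extents).
* A synthetic plantation generator that emulates the coarse-segmentation
  artifacts (rough ground, neighbour-crown contamination) with known ground
  truth, so every stage is testable without downloads.

The network trains on a small, hand-written reverse-mode autodiff engine
over numpy arrays; gradients are verified against finite differences in the
test suite.

## The model in brief

A normalized cloud (centroid 0, max extent 1) is voxelized at cell sizes
(0.01, 0.025, 0.1, 0.25). Per stage: features F are enhanced by
`F + IDWT2(cA, α·(cH, cV, cD))`, max-pooled per cell after a linear
projection (coordinates mean-pooled), refined by SGTramba — per group g,
attention output `concat_h Σ_j softmax_j(⟨q_i^h, k_j^h⟩/√(c/g)) · (v_j ⊙
pos(p_i − p_j))^h` with `pos` a perceptron over `[Δp ‖ sin/cos(2^i Δp)]`,
then group features ordered by the score `ReLU(BN(f W))` descending and
ascending through the state-space recurrence
`h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t u_t`, `y_t = C_t h_t` — and fused with
the previous stage through sigmoid gates. The decoder reverses the stages by
mapping de-pooling (each point receives its cell's feature) with skip
connections, and a softmax head labels every point. SCPO moves candidates
`X ← X_best ± r₁W₁X` (exploration, `W₁ = r₃a₁(cosh r₄ + u·sinh r₄ − 1)`,
`a₁ = −3.9t/T + 3m`, u = 0.388) then `X ← X + r₁₁(sinh r₁₁/cosh r₁₂)W₂(X_best − X)`
(exploitation, `W₂ = r₆·2t/T`), interleaved with PSO velocity updates.

## Worked example

```python
import numpy as np
from tmwsnet import (PlotSpec, TreeSpec, sample_plot, true_params,
                     extract_params, NetConfig, TrainConfig, train_model,
                     evaluate)
from tmwsnet.synthetic import make_dataset

# one noise-free tree: trunk 5 m x 0.15 m, ellipsoid crown 2 x 2 x 3 m
spec = TreeSpec(trunk_height=5.0, trunk_radius=0.15,
                crown_semi_axes=(2.0, 2.0, 3.0), crown_base_height=5.0)
cloud = sample_plot(PlotSpec(tree=spec, n_tree_points=6000,
                             n_ground_points=1000, n_neighbor_points=0,
                             ground_roughness=0.0, jitter_sd=0.0, seed=0))
print(true_params(spec))          # (11.0, 0.3, 4.0)
p = extract_params(cloud)
print(p.height, p.dbh, p.crown_diameter)

# train a small model on 8 synthetic samples, evaluate on 2 held out
clouds, _ = make_dataset(10, seed=11, plot_kwargs=dict(
    n_tree_points=2000, n_ground_points=600, n_neighbor_points=400))
cfg = NetConfig(channels=(16, 16, 16, 16), blocks_per_stage=1, G=24, k=12,
                n_heads=4, L=2, M=1, d_state=8, seed=0)
model, log = train_model(clouds[:8], [], cfg,
                         TrainConfig(epochs=20, batch_size=4, lr=3e-3, seed=0))
print(log[-1]["loss"], evaluate(model, clouds[8:]))
```

This prints (about two minutes on one CPU core):

```
(11.0, 0.3, 4.0)
10.86 0.300 3.91
0.1099 {'miou': 84.03, 'macc': 92.2, 'mprec': 91.15, 'mrec': 91.35, 'mf1': 91.25}
```

The extractor recovers the generator truth to 1.3% (height), 0.1% (DBH) and
2.2% (crown diameter); 20 epochs on 8 samples already reach 84% held-out
mIoU (more samples and epochs push this higher — see the reproduction
section).

## Command line

```sh
tmws synth --out data/ --n 25 --seed 7         # synthetic samples + manifest
tmws train --data data/ --config cfg.yaml --ckpt model.npz
tmws tune-lr --data data/ --lb 1e-8 --ub 1e-5  # SCPO learning-rate search
tmws predict --ckpt model.npz --in cloud.txt --out labeled.txt
tmws eval --ckpt model.npz --data data/ --report report.json
tmws params --in labeled.txt                   # height / DBH / crown diameter
```

The YAML config mirrors `NetConfig` (under `network:`) and `TrainConfig`
(under `training:`).

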