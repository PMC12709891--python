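"""TM-WSNet: encoder-decoder segmentation network over sparse voxel grids.

Pipeline: the normalized cloud is voxelized at the finest grid and each
occupied cell's aggregated features are linearly embedded (patch embedding).
Four encoder stages then each (i) wavelet-enhance the features, (ii) pool
them over a coarser cubic grid (projected max pooling of features, mean
pooling of coordinates), (iii) refine with grouped-attention/state-space
blocks, and (iv) fuse with the previous stage's output through the gated
multi-scale fusion block.  The decoder reverses the stages by mapping
de-pooling — each member point receives its cell's feature — concatenated
with the cached skip features and reduced linearly; a softmax head yields
per-point class probabilities.

Training minimises per-point cross-entropy with Adam; the initial learning
rate is either given or searched with the sinh/cosh-swarm optimizer using a
short probe run.  All stochastic choices (initialisation, shuffling, the
search) derive from explicit seeds, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concatenate
from .geometry_io import (GridPartition, LabeledCloud, build_grid,
                          estimate_normals_pca, normalize_unit)
from .metrics import compute_metrics, confusion
from .nn import Adam, LayerNorm, Linear, Module
from .scpo import SCPOConfig, tune_learning_rate
from .sgtramba import SGTrambaBlock
from .wgms import MSFF, PoolProjection, align_skip, dwt_enhance_t, wgrid_downsample

logger = logging.getLogger("tmwsnet")

__all__ = ["NetConfig", "TrainConfig", "StageCache", "TMWSNet",
           "patch_embed", "encoder_forward", "decoder_forward", "seg_head",
           "train_model", "predict", "evaluate", "save_checkpoint",
           "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``grid_sizes`` are cell edges on unit-extent-normalized coordinates,
    finest to coarsest; ``channels`` the per-stage widths.  ``use_sgtramba``
    and ``use_wgms`` are the ablation switches (plain grouped attention and
    plain pass-through fusion respectively).
    """

    grid_sizes: tuple = (0.01, 0.025, 0.1, 0.25)
    channels: tuple = (32, 64, 128, 256)
    blocks_per_stage: int = 2
    G: int = 64
    k: int = 16
    n_heads: int = 4
    L: int = 3
    M: int = 2
    d_state: int = 16
    n_classes: int = 2
    alpha: float = 2.0
    k_s: int = 9
    use_sgtramba: bool = True
    use_wgms: bool = True
    use_normals: bool = False
    include_position: bool = True
    seed: int = 0

    def __post_init__(self):
        gs = self.grid_sizes
        if any(b <= a for a, b in zip(gs, gs[1:])):
            raise ValueError("grid_sizes must be strictly increasing")
        if min(self.channels) < 1:
            raise ValueError("channels must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def in_dim(self) -> int:
        return 3 + (3 if self.use_normals else 0) + (3 if self.include_position else 0)


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 4
    lr: float | None = 1e-3          # None -> search with SCPO
    use_scpo: bool = False
    seed: int = 0
    max_steps: int | None = None
    lr_schedule: str = "constant"    # "constant" or "cosine" (per-epoch decay)
    probe_epochs: int = 3
    scpo_particles: int = 5
    scpo_iters: int = 4
    lr_bounds: tuple = (1e-8, 1e-5)
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr is not None and not 0 < self.lr < 1:
            raise ValueError("lr must lie in (0, 1)")


@dataclass
class StageCache:
    """Everything the decoder needs to reverse one encoder stage."""

    partition: GridPartition
    in_coords: np.ndarray
    skip_feats: Tensor
    out_coords: np.ndarray


class TMWSNet(Module):
    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        self.embed = Linear(cfg.in_dim, ch[0], rng)
        self.embed_norm = LayerNorm(ch[0])
        self.projs, self.blocks, self.fusions, self.decoders = [], [], [], []
        for s in range(4):
            c_in = ch[s - 1] if s > 0 else ch[0]
            c_out = ch[s]
            self.projs.append(PoolProjection(
                Parameter(rng.standard_normal((c_in, c_out)) / np.sqrt(c_in))))
            self.blocks.append([
                SGTrambaBlock(c_out, rng, G=cfg.G, k=cfg.k, n_heads=cfg.n_heads,
                              L=cfg.L if cfg.use_sgtramba else 0, M=cfg.M,
                              d_state=cfg.d_state, use_mamba=cfg.use_sgtramba)
                for _ in range(cfg.blocks_per_stage)])
            if s > 0:
                self.fusions.append(MSFF(ch[s - 1], c_out, rng, k_s=cfg.k_s,
                                         residual=True))
            self.decoders.append(Linear(c_out + c_in, c_in, rng))
        # per-stage normalisation keeps residual/wavelet amplification bounded
        self.stage_norms = [LayerNorm(ch[s]) for s in range(4)]
        self.head_norm = LayerNorm(ch[0])
        self.head = Linear(ch[0], cfg.n_classes, rng)
        # register sublists for parameter collection
        self._proj_params = [p.U for p in self.projs]

    # -- stages -----------------------------------------------------------
    def patch_embed(self, coords: np.ndarray, normals: np.ndarray | None):
        """Voxelize at the finest cell and embed per-voxel aggregates."""
        if len(coords) == 0:
            raise ValueError("empty cloud")
        grid = build_grid(coords, self.cfg.grid_sizes[0])
        vid = grid.voxel_id
        # canonical accumulation order (voxel id, then xyz) so voxel means are
        # bitwise identical under any permutation of the input points
        canon = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], vid))
        c_sorted, v_sorted = coords[canon], vid[canon]
        counts = np.bincount(vid, minlength=grid.n_voxels).astype(np.float64)
        mean_coords = np.zeros((grid.n_voxels, 3))
        np.add.at(mean_coords, v_sorted, c_sorted)
        mean_coords /= counts[:, None]
        ijk = np.floor((c_sorted - grid.origin) / grid.cell)
        centers = grid.origin + (ijk + 0.5) * grid.cell
        offsets = np.zeros((grid.n_voxels, 3))
        np.add.at(offsets, v_sorted, c_sorted - centers)
        offsets /= counts[:, None]
        feats = [offsets]
        if self.cfg.use_normals:
            if normals is None:
                raise ValueError("config expects normals but the cloud has none")
            mn = np.zeros((grid.n_voxels, 3))
            np.add.at(mn, v_sorted, normals[canon])
            mn /= counts[:, None]
            feats.append(mn)
        if self.cfg.include_position:
            feats.append(mean_coords)
        raw = Tensor(np.concatenate(feats, axis=1))
        emb = self.embed_norm(self.embed(raw))
        return emb, mean_coords, grid

    def encoder(self, emb: Tensor, coords: np.ndarray):
        F, cur = emb, coords
        caches: list[StageCache] = []
        AM_prev, prev_coords = None, None
        for s in range(4):
            if self.cfg.use_wgms:
                F = dwt_enhance_t(F, self.cfg.alpha)
            grid = build_grid(cur, self.cfg.grid_sizes[s])
            if grid.n_voxels == 0:
                raise ValueError("grid too coarse: a stage pooled to 0 voxels")
            skip = F
            coords2, F2, part = wgrid_downsample(cur, F, grid, self.projs[s])
            F2 = self.stage_norms[s](F2)
            for block in self.blocks[s]:
                F2, _ = block(coords2, F2)
            if s == 0 or not self.cfg.use_wgms:
                AM = F2
            else:
                aligned = align_skip(AM_prev, prev_coords, coords2)
                AM = self.fusions[s - 1](aligned, F2, coords2)
            caches.append(StageCache(partition=part, in_coords=cur,
                                     skip_feats=skip, out_coords=coords2))
            AM_prev, prev_coords = AM, coords2
            cur, F = coords2, AM
        return F, caches

    def decoder(self, deep: Tensor, caches: list[StageCache]) -> Tensor:
        feats = deep
        for s in range(3, -1, -1):
            cache = caches[s]
            up = feats[cache.partition.voxel_id]           # mapping de-pooling
            merged = concatenate([up, cache.skip_feats], axis=1)
            feats = self.decoders[s](merged).relu()
        return feats

    def seg_head(self, point_feats: Tensor) -> Tensor:
        """Per-point class log-probabilities (rows of softmax sum to 1)."""
        return self.head(self.head_norm(point_feats)).log_softmax(axis=-1)

    def forward(self, coords: np.ndarray, normals: np.ndarray | None = None):
        emb, vox_coords, patch_grid = self.patch_embed(coords, normals)
        deep, caches = self.encoder(emb, vox_coords)
        vox_feats = self.decoder(deep, caches)
        point_feats = vox_feats[patch_grid.voxel_id]
        return self.seg_head(point_feats)

    __call__ = forward


# functional aliases mirroring the operation-level surface ------------------


def patch_embed(cloud: LabeledCloud, model: TMWSNet):
    """Voxel features + partition for a normalized cloud."""
    return model.patch_embed(cloud.coords, cloud.normals)


def encoder_forward(embedded: Tensor, coords: np.ndarray, model: TMWSNet):
    return model.encoder(embedded, coords)


def decoder_forward(deep: Tensor, caches: list[StageCache], model: TMWSNet):
    return model.decoder(deep, caches)


def seg_head(point_feats, model: TMWSNet) -> Tensor:
    feats = point_feats if isinstance(point_feats, Tensor) else Tensor(point_feats)
    return model.seg_head(feats)


# ---------------------------------------------------------------------------
# training / inference


def _prepare(cloud: LabeledCloud, cfg: NetConfig):
    norm, tf = normalize_unit(cloud)
    normals = None
    if cfg.use_normals:
        if norm.normals is None:
            norm = estimate_normals_pca(norm, k=min(16, len(norm)))
        normals = norm.normals
    return norm.coords, normals, cloud.labels


def _loss(logp: Tensor, labels: np.ndarray) -> Tensor:
    n = len(labels)
    picked = logp[np.arange(n), labels]
    return picked.sum() * (-1.0 / n)


def _run_epochs(model, opt, prepared, rng, batch_size, n_epochs, max_steps,
                log, val_prepared=None, lr_schedule="constant"):
    step = 0
    lr0 = opt.lr
    for epoch in range(n_epochs):
        if lr_schedule == "cosine":
            opt.lr = lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / n_epochs))
        order = rng.permutation(len(prepared))
        ep_loss, seen = 0.0, 0
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for bi in batch:
                coords, normals, labels = prepared[bi]
                logp = model(coords, normals)
                loss = _loss(logp, labels)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite loss at step {step}")
                loss.backward(np.array(1.0 / len(batch)))
                batch_loss += float(loss.data) / len(batch)
            opt.step()
            ep_loss += batch_loss
            seen += 1
            step += 1
            if max_steps is not None and step >= max_steps:
                log.append({"epoch": epoch, "step": step, "loss": ep_loss / seen})
                return step
        entry = {"epoch": epoch, "step": step, "loss": ep_loss / max(seen, 1)}
        if val_prepared is not None:
            entry["val_loss"] = _dataset_loss(model, val_prepared)
        log.append(entry)
    return step


def _dataset_loss(model, prepared) -> float:
    model.eval()
    total = 0.0
    for coords, normals, labels in prepared:
        total += float(_loss(model(coords, normals), labels).data)
    model.train()
    return total / len(prepared)


def train_model(train_set, val_set, net_cfg: NetConfig, train_cfg: TrainConfig):
    """Train on labeled clouds; returns (model, log) and saves a checkpoint.

    The learning rate comes from ``train_cfg.lr`` unless ``use_scpo`` (or
    ``lr is None``), in which case a short probe run per candidate drives the
    sinh/cosh-swarm search over ``lr_bounds`` in log10 space.
    """
    if not train_set:
        raise ValueError("empty training set")
    for c in train_set:
        if c.labels is None:
            raise ValueError("training clouds must be labeled")
    prepared = [_prepare(c, net_cfg) for c in train_set]
    val_prepared = [_prepare(c, net_cfg) for c in val_set] if val_set else None
    log: list[dict] = []

    lr = train_cfg.lr
    if train_cfg.use_scpo or lr is None:
        probe_prep = prepared[: max(2, len(prepared) // 4)]
        probe_val = val_prepared or probe_prep

        def probe(candidate_lr: float) -> float:
            pm = TMWSNet(net_cfg)
            popt = Adam(pm.parameters(), lr=candidate_lr)
            prng = np.random.default_rng(train_cfg.seed)
            _run_epochs(pm, popt, probe_prep, prng, train_cfg.batch_size,
                        train_cfg.probe_epochs, None, [])
            return _dataset_loss(pm, probe_val)

        lb, ub = train_cfg.lr_bounds
        scfg = SCPOConfig(n_particles=train_cfg.scpo_particles,
                          max_iter=train_cfg.scpo_iters, seed=train_cfg.seed)
        lr, info = tune_learning_rate(probe, lb=lb, ub=ub, cfg=scfg)
        logger.info("SCPO learning-rate search: lr=%.3g after %d probes",
                    lr, info["n_evals"])
        log.append({"scpo_lr": lr, **{k: info[k] for k in ("loss", "n_evals")}})

    model = TMWSNet(net_cfg)
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(train_cfg.seed + 1)
    _run_epochs(model, opt, prepared, rng, train_cfg.batch_size,
                train_cfg.epochs, train_cfg.max_steps, log,
                val_prepared=val_prepared, lr_schedule=train_cfg.lr_schedule)
    model.eval()
    if train_cfg.checkpoint_path:
        save_checkpoint(model, train_cfg.checkpoint_path)
    return model, log


def predict(model: TMWSNet, cloud: LabeledCloud) -> LabeledCloud:
    """Normalize, forward, argmax; labels written into a new cloud."""
    model.eval()
    coords, normals, _ = _prepare(cloud, model.cfg)
    logp = model(coords, normals)
    labels = np.argmax(logp.data, axis=1)
    return LabeledCloud(cloud.coords, cloud.normals, labels,
                        source_id=cloud.source_id)


def evaluate(model: TMWSNet, clouds) -> dict:
    """Pooled confusion-based metrics over a list of labeled clouds."""
    preds, truths = [], []
    for cloud in clouds:
        out = predict(model, cloud)
        preds.append(out.labels)
        truths.append(cloud.labels)
    counts = confusion(np.concatenate(preds), np.concatenate(truths),
                       model.cfg.n_classes)
    report = compute_metrics(counts)
    return {"miou": report.miou, "macc": report.macc, "mprec": report.mprec,
            "mrec": report.mrec, "mf1": report.mf1}


def save_checkpoint(model: TMWSNet, path) -> None:
    """Single-file archive: versioned config JSON + all weight arrays."""
    arrays = model.state_arrays()
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})


def load_checkpoint(path) -> TMWSNet:
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                 allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError("incompatible checkpoint version")
        cfg_d = meta["config"]
        cfg_d["grid_sizes"] = tuple(cfg_d["grid_sizes"])
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg = NetConfig(**cfg_d)
        model = TMWSNet(cfg)
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model.load_state_arrays(arrays)
    model.eval()
    return model
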