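"""Synthetic single-tree LiDAR samples with coarse-segmentation artifacts.

Real training samples in this problem are produced by a graph-based coarse
isolation of a plantation scan: one target tree plus the artifacts that step
cannot remove — a patch of rough ground, and fragments of neighboring crowns
that overlap the target's canopy.  This module generates labeled clouds with
exactly that structure (label 1 = target tree, label 0 = everything else)
together with ground-truth structural parameters, so the network, metrics and
parameter extraction are all testable without field data.

A tree is a cylinder trunk (lateral surface) topped by a filled ellipsoid
crown; the crown is filled rather than a shell because LiDAR returns
penetrate canopies, and a filled crown keeps the two classes non-separable by
height alone once a neighbor crown fragment is added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("tmwsnet")

from .geometry_io import LabeledCloud, write_cloud_txt

__all__ = ["TreeSpec", "PlotSpec", "sample_tree", "sample_plot", "true_params",
           "make_dataset", "write_dataset", "DEFAULT_RANGES"]


@dataclass
class TreeSpec:
    """Morphology of one tree (meters; lean in degrees from vertical)."""

    trunk_height: float = 5.0
    trunk_radius: float = 0.15
    crown_semi_axes: tuple = (2.0, 2.0, 3.0)
    crown_base_height: float = 4.0
    lean: float = 0.0

    def __post_init__(self):
        rx, ry, rz = self.crown_semi_axes
        if min(self.trunk_height, self.trunk_radius, rx, ry, rz) <= 0:
            raise ValueError("all lengths must be positive")
        if self.crown_base_height > self.trunk_height:
            raise ValueError("crown_base_height must not exceed trunk_height")
        if not (0 <= self.lean < 30):
            raise ValueError("lean must be in [0, 30) degrees")


@dataclass
class PlotSpec:
    """One coarse-segmented sample: target tree + ground + neighbor fragment."""

    tree: TreeSpec = field(default_factory=TreeSpec)
    ground_extent: float = 8.0
    ground_roughness: float = 0.05
    n_tree_points: int = 4000
    n_ground_points: int = 1200
    n_neighbor_points: int = 800
    neighbor_offset: float = 3.0
    jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_tree_points < 1:
            raise ValueError("n_tree_points must be >= 1")
        if min(self.n_ground_points, self.n_neighbor_points) < 0:
            raise ValueError("point counts must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def _ellipsoid_interior(n: int, semi: tuple, rng: np.random.Generator) -> np.ndarray:
    """n points uniform inside an axis-aligned ellipsoid centered at 0."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None] * np.asarray(semi)


def sample_tree(spec: TreeSpec, n: int, rng: np.random.Generator,
                jitter_sd: float = 0.0) -> LabeledCloud:
    """n points on/in one tree, all labeled 1; trunk:crown point ratio 1:4."""
    if n < 1:
        raise ValueError("n must be >= 1")
    n_trunk = max(1, int(round(n / 5))) if n >= 2 else n
    n_crown = n - n_trunk
    theta = rng.random(n_trunk) * 2 * np.pi
    trunk = np.column_stack([
        spec.trunk_radius * np.cos(theta),
        spec.trunk_radius * np.sin(theta),
        rng.random(n_trunk) * spec.trunk_height,
    ])
    rx, ry, rz = spec.crown_semi_axes
    crown = _ellipsoid_interior(n_crown, (rx, ry, rz), rng)
    crown[:, 2] += spec.crown_base_height + rz
    pts = np.vstack([trunk, crown]) if n_crown else trunk
    if spec.lean > 0:
        a = np.deg2rad(spec.lean)
        rot = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
        pts = pts @ rot.T
    if jitter_sd > 0:
        pts = pts + rng.standard_normal(pts.shape) * jitter_sd
    return LabeledCloud(pts, labels=np.ones(len(pts), dtype=np.int64))


def sample_plot(spec: PlotSpec) -> LabeledCloud:
    """One labeled sample: tree (1) + rough ground (0) + neighbor crown (0)."""
    rng = np.random.default_rng(spec.seed)
    parts, labels = [], []
    tree = sample_tree(spec.tree, spec.n_tree_points, rng)
    parts.append(tree.coords)
    labels.append(np.ones(len(tree), dtype=np.int64))
    if spec.n_ground_points:
        g = np.column_stack([
            (rng.random(spec.n_ground_points) - 0.5) * spec.ground_extent,
            (rng.random(spec.n_ground_points) - 0.5) * spec.ground_extent,
            rng.standard_normal(spec.n_ground_points) * spec.ground_roughness,
        ])
        parts.append(g)
        labels.append(np.zeros(spec.n_ground_points, dtype=np.int64))
    if spec.n_neighbor_points:
        rx, ry, rz = spec.tree.crown_semi_axes
        azim = rng.random() * 2 * np.pi
        shift = np.array([np.cos(azim), np.sin(azim), 0.0]) * spec.neighbor_offset
        # upper hemisphere of a neighbor crown leaning into the target canopy
        frag = np.empty((0, 3))
        while len(frag) < spec.n_neighbor_points:
            cand = _ellipsoid_interior(2 * spec.n_neighbor_points, (rx, ry, rz), rng)
            frag = np.vstack([frag, cand[cand[:, 2] >= 0]])
        frag = frag[: spec.n_neighbor_points]
        frag[:, 2] += spec.tree.crown_base_height + rz
        frag += shift
        parts.append(frag)
        labels.append(np.zeros(spec.n_neighbor_points, dtype=np.int64))
    coords = np.vstack(parts)
    labs = np.concatenate(labels)
    logger.debug("plot seed=%d: %d points, tree fraction %.3f",
                 spec.seed, len(labs), labs.mean())
    if spec.jitter_sd > 0:
        coords = coords + rng.standard_normal(coords.shape) * spec.jitter_sd
    perm = rng.permutation(len(coords))
    return LabeledCloud(coords[perm], labels=labs[perm],
                        source_id=f"synthetic-plot-{spec.seed}")


def true_params(spec: TreeSpec) -> tuple[float, float, float]:
    """(height, DBH, crown diameter) implied by the generator geometry."""
    rx, ry, rz = spec.crown_semi_axes
    height = spec.crown_base_height + 2 * rz
    dbh = 2 * spec.trunk_radius
    crown_diameter = rx + ry
    return height, dbh, crown_diameter


#: field -> (low, high) uniform ranges emulating morphology variation among
#: mature plantation trees (trunk height, crown shape, lean).
DEFAULT_RANGES = {
    "trunk_height": (4.0, 7.0),
    "trunk_radius": (0.10, 0.20),
    "crown_rx": (1.6, 2.8),
    "crown_ry": (1.6, 2.8),
    "crown_rz": (2.0, 3.5),
    "crown_base_frac": (0.6, 0.9),  # crown base as a fraction of trunk height
    "lean": (0.0, 5.0),
}


def make_dataset(n_samples: int, spec_ranges: dict | None = None, seed: int = 0,
                 plot_kwargs: dict | None = None):
    """Draw ``n_samples`` plots with specs uniform in ``spec_ranges``.

    Returns ``(clouds, truths)`` where ``truths[i]`` is the
    (height, dbh, crown_diameter) triple of sample i's target tree.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = dict(DEFAULT_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}")
    rng = np.random.default_rng(seed)

    def draw(key):
        lo, hi = ranges[key]
        return lo + (hi - lo) * rng.random()

    clouds, truths = [], []
    for i in range(n_samples):
        th = draw("trunk_height")
        spec = TreeSpec(
            trunk_height=th,
            trunk_radius=draw("trunk_radius"),
            crown_semi_axes=(draw("crown_rx"), draw("crown_ry"), draw("crown_rz")),
            crown_base_height=th * draw("crown_base_frac"),
            lean=draw("lean"),
        )
        plot = PlotSpec(tree=spec, seed=int(rng.integers(0, 2**31 - 1)),
                        **(plot_kwargs or {}))
        clouds.append(sample_plot(plot))
        truths.append(true_params(spec))
    return clouds, truths


def write_dataset(out_dir, n_samples: int, seed: int = 0,
                  spec_ranges: dict | None = None, plot_kwargs: dict | None = None):
    """Write samples as txt clouds plus a CSV manifest of true parameters."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    clouds, truths = make_dataset(n_samples, spec_ranges, seed, plot_kwargs)
    rows = []
    for i, (cloud, (h, dbh, cd)) in enumerate(zip(clouds, truths)):
        path = os.path.join(out_dir, f"sample_{i:04d}.txt")
        write_cloud_txt(cloud, path)
        rows.append({"path": path, "height": h, "dbh": dbh, "crown_diameter": cd})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
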