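"""Point-cloud data model and I/O.

The universal in-memory unit is :class:`LabeledCloud`: xyz coordinates in
meters (or normalized units after :func:`normalize_unit`), optional unit
normals, and an optional binary label per point (1 = tree, 0 = other).
Clouds are exchanged as plain-text files, one point per line, columns
``x y z [nx ny nz] [label]``, whitespace- or comma-separated, ``#`` comment
lines skipped — the export convention of single-tree samples produced by
coarse pre-segmentation and manual labeling.  ASCII PLY is read as a
convenience.

Also here: PCA normal estimation, unit-extent normalization, the cubic grid
partition reused by patch embedding, wavelet grid pooling and the decoder,
and the seeded train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("tmwsnet")

__all__ = [
    "LabeledCloud",
    "GridPartition",
    "Transform",
    "read_cloud_txt",
    "read_cloud_ply",
    "write_cloud_txt",
    "estimate_normals_pca",
    "normalize_unit",
    "build_grid",
    "split_dataset",
]


@dataclass
class LabeledCloud:
    """N points with optional normals and optional binary labels."""

    coords: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("coords must be a non-empty N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.coords.shape:
                raise ValueError("normals must match coords shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-4):
                raise ValueError("normals must be unit length (within 1e-4)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.coords),):
                raise ValueError("labels must be a length-N vector")
            if not np.all(np.isin(self.labels, (0, 1))):
                raise ValueError("labels must take values in {0, 1}")
            self.labels = self.labels.astype(np.int64)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class GridPartition:
    """Partition of points into non-overlapping axis-aligned cubic cells.

    Cells are half-open cubes ``[origin + k*cell, origin + (k+1)*cell)`` with
    the origin at the component-wise minimum, so membership is deterministic
    and invariant to the input point order.  Voxel ids are assigned in
    lexicographic order of the integer cell coordinates.
    """

    cell: float
    origin: np.ndarray
    voxel_id: np.ndarray  # N ints in [0, n_voxels)
    voxel_table: dict = field(repr=False)  # id -> member point indices
    n_voxels: int

    def members(self, vid: int) -> np.ndarray:
        return self.voxel_table[vid]


@dataclass
class Transform:
    """Record of the centering/scaling applied by :func:`normalize_unit`."""

    center: np.ndarray
    scale: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.center) / self.scale

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return coords * self.scale + self.center


# ---------------------------------------------------------------------------
# readers / writers


def _parse_lines(lines, n_cols: int, path: str) -> np.ndarray:
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}: line {lineno}: expected {n_cols} columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise ValueError(f"{path}: line {lineno}: {e}") from None
    if not rows:
        raise ValueError(f"{path}: no points")
    return np.asarray(rows, dtype=np.float64)


def read_cloud_txt(path, has_normals: bool = False, has_labels: bool = False) -> LabeledCloud:
    """Read the plain-text dialect: columns ``x y z [nx ny nz] [label]``."""
    n_cols = 3 + (3 if has_normals else 0) + (1 if has_labels else 0)
    with open(path) as fh:
        data = _parse_lines(fh, n_cols, str(path))
    coords = data[:, :3]
    normals = data[:, 3:6] if has_normals else None
    labels = None
    if has_labels:
        raw = data[:, -1]
        if not np.all(np.isin(raw, (0.0, 1.0))):
            bad = raw[~np.isin(raw, (0.0, 1.0))][0]
            raise ValueError(f"{path}: label value {bad} outside {{0, 1}}")
        labels = raw.astype(np.int64)
    return LabeledCloud(coords, normals, labels, source_id=str(path))


def read_cloud_ply(path) -> LabeledCloud:
    """Read an ASCII PLY file (convenience; x/y/z and optional nx/ny/nz)."""
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = fh.readline().split()
        if len(fmt) < 2 or fmt[1] != "ascii":
            raise ValueError(f"{path}: only ascii PLY is supported")
        n_vertex, props = 0, []
        for line in fh:
            tok = line.split()
            if tok[0] == "element" and tok[1] == "vertex":
                n_vertex = int(tok[2])
            elif tok[0] == "property" and n_vertex:
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        rows = [fh.readline().split() for _ in range(n_vertex)]
    data = np.asarray(rows, dtype=np.float64)
    cols = {p: i for i, p in enumerate(props)}
    coords = data[:, [cols["x"], cols["y"], cols["z"]]]
    normals = None
    if all(p in cols for p in ("nx", "ny", "nz")):
        normals = data[:, [cols["nx"], cols["ny"], cols["nz"]]]
    return LabeledCloud(coords, normals, source_id=str(path))


def write_cloud_txt(cloud: LabeledCloud, path) -> None:
    """Write the txt dialect; columns follow the cloud's optional fields."""
    blocks = [cloud.coords]
    fmt = ["%.6f"] * 3
    if cloud.normals is not None:
        blocks.append(cloud.normals)
        fmt += ["%.6f"] * 3
    if cloud.labels is not None:
        blocks.append(cloud.labels[:, None].astype(np.float64))
        fmt += ["%d"]
    np.savetxt(path, np.hstack(blocks), fmt=" ".join(fmt))


# ---------------------------------------------------------------------------
# geometry


def estimate_normals_pca(cloud: LabeledCloud, k: int) -> LabeledCloud:
    """Per-point normal = smallest-eigenvalue eigenvector of the k-NN covariance.

    Sign convention: positive z component; if the z component is zero, positive
    x, then positive y.
    """
    n = len(cloud)
    if k < 3 or k > n:
        raise ValueError(f"k must be in [3, N={n}], got {k}")
    nn = NearestNeighbors(n_neighbors=k).fit(cloud.coords)
    _, idx = nn.kneighbors(cloud.coords)
    nbrs = cloud.coords[idx]  # N x k x 3
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # deterministic sign: positive z, then positive x, then positive y
    nz, nx, ny = normals[:, 2], normals[:, 0], normals[:, 1]
    tol = 1e-12
    sign = np.where(np.abs(nz) > tol, np.sign(nz),
                    np.where(np.abs(nx) > tol, np.sign(nx), np.sign(ny)))
    sign[sign == 0] = 1.0
    normals *= sign[:, None]
    return replace(cloud, normals=normals)


def normalize_unit(cloud: LabeledCloud) -> tuple[LabeledCloud, Transform]:
    """Center at the centroid and scale so the maximum axis extent is 1."""
    center = cloud.coords.mean(axis=0)
    extent = cloud.coords.max(axis=0) - cloud.coords.min(axis=0)
    scale = float(extent.max())
    if scale <= 0.0:
        logger.warning("degenerate cloud (zero extent); scale set to 1")
        scale = 1.0
    tf = Transform(center=center, scale=scale)
    return replace(cloud, coords=tf.apply(cloud.coords)), tf


def build_grid(coords: np.ndarray, cell: float) -> GridPartition:
    """Assign each point to a half-open cubic cell of edge ``cell``."""
    if cell <= 0:
        raise ValueError("cell must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    origin = coords.min(axis=0)
    ijk = np.floor((coords - origin) / cell).astype(np.int64)
    # ids in lexicographic order of (ix, iy, iz): deterministic, order-invariant
    uniq, inverse = np.unique(ijk, axis=0, return_inverse=True)
    n_voxels = len(uniq)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(n_voxels + 1))
    table = {v: order[bounds[v]:bounds[v + 1]] for v in range(n_voxels)}
    return GridPartition(cell=float(cell), origin=origin, voxel_id=inverse,
                         voxel_table=table, n_voxels=n_voxels)


def split_dataset(ids, ratio=(4, 1), seed: int = 0):
    """Random train/test split at ``ratio`` (train:test), seeded.

    The train count is the nearest integer to ``n * r/(r+1)`` with ties toward
    train, so 600 ids at 4:1 give exactly 480/120.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("empty id list")
    if np.isscalar(ratio):
        frac = float(ratio) / (float(ratio) + 1.0)
    else:
        tr, te = ratio
        if tr <= 0 or te <= 0:
            raise ValueError("ratio parts must be positive")
        frac = tr / (tr + te)
    n = len(ids)
    n_train = int(np.floor(n * frac + 0.5))  # round half toward train
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test
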