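"""Point-cloud primitives for lung-surface registration.

Normal estimation and surface-variation analysis use the standard local
covariance (PCA) construction over k-nearest-neighbour patches.  Adjacency
is a symmetric k-NN graph whose node-arc incidence matrix drives the
local-affine stiffness regularizer of the registration energies; k-NN
adjacency stands in for a surface triangulation, whose typical valence on a
closed surface is about six.

All coordinates are millimetres.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "AdjacencyGraph",
    "CorrespondenceSet",
    "estimate_normals",
    "surface_variation",
    "build_adjacency",
    "closest_points",
    "simplify",
]


@dataclass
class PointCloud:
    """An unordered 3-D point set, optionally with unit normals and ids.

    Parameters
    ----------
    points
        ``(n, 3)`` coordinates in millimetres; must be finite, ``n >= 1``.
    normals
        Optional ``(n, 3)`` unit vectors (checked to 1e-9).
    ids
        Optional unique integer labels; carried through decimation so that
        decimated clouds can be traced back to their dense parent.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normals must be unit length (|n| = 1 +/- 1e-9)")
        if self.ids is not None:
            self.ids = np.ascontiguousarray(self.ids, dtype=np.int64)
            if self.ids.shape != (self.points.shape[0],):
                raise ValueError("ids must be a length-n integer vector")
            if np.unique(self.ids).size != self.ids.size:
                raise ValueError("ids must be unique")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def with_ids(self) -> "PointCloud":
        """Return the cloud with ids materialized (0..n-1 when absent)."""
        if self.ids is not None:
            return self
        return PointCloud(self.points, self.normals, np.arange(self.n))


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour graph over a source cloud.

    ``incidence`` is the sparse ``|E| x n`` node-arc matrix with +1 at the
    first and -1 at the second endpoint of each edge; it is the
    connectivity matrix of the stiffness regularizer.
    """

    n_nodes: int
    edges: np.ndarray  # (|E|, 2) int, each row (i, j) with i < j, unique
    incidence: sparse.csr_matrix
    connected: bool = True

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class CorrespondenceSet:
    """Per-source-point closest-target-point assignment.

    Holds, for each deformed source point, its Euclidean nearest target
    point ``u_i``, that point's unit normal ``n_i``, a weight ``w_i`` in
    [0, 1] and the current Euclidean distance (mm).
    """

    target_points: np.ndarray
    target_normals: np.ndarray
    weights: np.ndarray
    distances: np.ndarray
    indices: np.ndarray | None = None  # indices into the target cloud

    def __post_init__(self) -> None:
        self.target_points = np.asarray(self.target_points, dtype=float)
        self.target_normals = np.asarray(self.target_normals, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        n = self.target_points.shape[0]
        if self.target_normals.shape != (n, 3):
            raise ValueError("target_normals shape mismatch")
        if self.weights.shape != (n,) or self.distances.shape != (n,):
            raise ValueError("weights/distances shape mismatch")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        if (self.distances < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.target_points.shape[0]


def _knn_neighbourhoods(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's neighbourhood: itself plus its k nearest."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    return idx


def _local_covariance_eig(points: np.ndarray, k: int):
    idx = _knn_neighbourhoods(points, k)
    nbrs = points[idx]  # (n, k+1, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    return evals, evecs


def estimate_normals(cloud: PointCloud, k: int = 12) -> PointCloud:
    """Estimate per-point unit normals by local covariance analysis.

    The normal at a point is the eigenvector of the covariance matrix of
    the point's neighbourhood (the point plus its ``k`` nearest
    neighbours) belonging to the smallest eigenvalue.  Signs are fixed by
    the centroid-outward heuristic: a normal is flipped so that
    ``n . (p - centroid) >= 0``; exact ties are left as computed.  The
    registration energies are invariant to normal sign, so the heuristic
    only serves reproducible output.

    Raises
    ------
    ValueError
        If ``k < 3``, ``k >= n``, or some neighbourhood is degenerate
        (all its points coincide).
    """
    if k < 3:
        raise ValueError("normal estimation requires k >= 3")
    if k >= cloud.n:
        raise ValueError(f"k={k} must be smaller than the cloud size n={cloud.n}")
    evals, evecs = _local_covariance_eig(cloud.points, k)
    total = evals.sum(axis=1)
    bad = np.flatnonzero(total <= 0.0)
    if bad.size:
        raise ValueError(
            f"degenerate neighbourhood (all points coincident) at point {bad[0]}"
        )
    normals = evecs[:, :, 0]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    centroid = cloud.points.mean(axis=0)
    outward = np.einsum("ij,ij->i", normals, cloud.points - centroid)
    normals[outward < 0] *= -1.0
    return PointCloud(cloud.points, normals, cloud.ids)


def surface_variation(cloud: PointCloud, k: int = 12) -> np.ndarray:
    """Surface variation lambda_0 / (lambda_0 + lambda_1 + lambda_2).

    Eigenvalues of the same k-NN covariance as :func:`estimate_normals`,
    sorted ascending.  Near 0 on locally flat patches, up to 1/3 for
    isotropic scatter; degenerate neighbourhoods (zero total variance) are
    defined as 0.  Flat regions are the ones where a point-to-point
    distance term cannot sense tangential motion.
    """
    if k < 3:
        raise ValueError("surface variation requires k >= 3")
    if k >= cloud.n:
        raise ValueError(f"k={k} must be smaller than the cloud size n={cloud.n}")
    evals, _ = _local_covariance_eig(cloud.points, k)
    evals = np.clip(evals, 0.0, None)
    total = evals.sum(axis=1)
    out = np.zeros(cloud.n)
    ok = total > 0
    out[ok] = evals[ok, 0] / total[ok]
    return out


def build_adjacency(cloud: PointCloud, k: int = 6) -> AdjacencyGraph:
    """Symmetric k-nearest-neighbour adjacency with node-arc incidence.

    Edge ``(i, j)`` is present iff ``j`` is among ``i``'s ``k`` nearest
    neighbours or vice versa.  A warning is emitted (and the ``connected``
    flag cleared) when the graph is disconnected; the optimizers refuse
    disconnected graphs because the stiffness regularizer then no longer
    ties all local transforms together.
    """
    n = cloud.n
    if k < 1:
        raise ValueError("adjacency requires k >= 1")
    if n < 2:
        raise ValueError("adjacency requires at least two points")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cloud size n={n}")
    idx = _knn_neighbourhoods(cloud.points, k)  # (n, k+1), usually self first
    rows = np.arange(n)
    self_pos = idx == rows[:, None]
    # drop the self column (or the last neighbour when duplicates hide self)
    drop = np.where(self_pos.any(axis=1), self_pos.argmax(axis=1), k)
    keep = np.ones((n, k + 1), dtype=bool)
    keep[rows, drop] = False
    jj = idx[keep].reshape(n, k)
    ii = np.repeat(rows, k)
    pairs = np.sort(np.column_stack([ii, jj.ravel()]), axis=1)
    edges = np.unique(pairs, axis=0)
    e = edges.shape[0]
    data = np.concatenate([np.ones(e), -np.ones(e)])
    row = np.concatenate([np.arange(e), np.arange(e)])
    col = np.concatenate([edges[:, 0], edges[:, 1]])
    incidence = sparse.csr_matrix((data, (row, col)), shape=(e, n))
    adj = sparse.csr_matrix(
        (np.ones(2 * e), (np.concatenate([edges[:, 0], edges[:, 1]]),
                          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    n_comp, _ = connected_components(adj, directed=False)
    connected = n_comp == 1
    if not connected:
        warnings.warn(
            f"adjacency graph is disconnected ({n_comp} components); "
            "the registration optimizers will refuse this graph",
            stacklevel=2,
        )
    return AdjacencyGraph(n_nodes=n, edges=edges, incidence=incidence,
                          connected=connected)


def closest_points(
    deformed_source: PointCloud,
    target: PointCloud,
    weighting: str = "uniform",
    tree: cKDTree | None = None,
) -> CorrespondenceSet:
    """Euclidean nearest-target-point correspondences.

    For each deformed source point the nearest target point, its normal
    and the distance are recorded.  ``weighting='uniform'`` assigns
    ``w_i = 1``; ``'robust'`` zeroes the weight of points whose distance
    exceeds ``median + 3 * MAD`` of the current distances.  The target is
    static across a registration, so callers may pass a prebuilt
    ``cKDTree`` and reuse it.
    """
    if target.normals is None:
        raise ValueError("target cloud must carry normals")
    if tree is None:
        tree = cKDTree(target.points)
    dist, idx = tree.query(deformed_source.points, k=1)
    if weighting == "uniform":
        w = np.ones(deformed_source.n)
    elif weighting == "robust":
        med = np.median(dist)
        mad = np.median(np.abs(dist - med))
        w = (dist <= med + 3.0 * mad).astype(float)
    else:
        raise ValueError(f"unknown weighting rule: {weighting!r}")
    return CorrespondenceSet(
        target_points=target.points[idx],
        target_normals=target.normals[idx],
        weights=w,
        distances=dist,
        indices=idx,
    )


def simplify(
    cloud: PointCloud,
    n_target: int,
    method: str = "random",
    seed: int = 0,
    k: int = 12,
) -> PointCloud:
    """Decimate a cloud to ``n_target`` member points.

    ``'random'`` samples uniformly without replacement; ``'curvature'``
    samples with probability proportional to surface variation plus a
    uniform floor (0.05) so that flat regions stay represented;
    ``'mixed'`` takes half by each rule.  Deterministic under ``seed``;
    ids are preserved (materialized as 0..n-1 when absent).
    """
    cloud = cloud.with_ids()
    n = cloud.n
    if not 1 <= n_target <= n:
        raise ValueError(f"n_target={n_target} must lie in [1, {n}]")
    if n_target == n:
        return cloud
    rng = np.random.default_rng(seed)
    if method == "random":
        sel = rng.choice(n, size=n_target, replace=False)
    elif method == "curvature":
        w = surface_variation(cloud, k=min(k, n - 1)) + 0.05
        sel = rng.choice(n, size=n_target, replace=False, p=w / w.sum())
    elif method == "mixed":
        w = surface_variation(cloud, k=min(k, n - 1)) + 0.05
        half = n_target // 2
        first = rng.choice(n, size=half, replace=False, p=w / w.sum())
        pool = np.setdiff1d(np.arange(n), first)
        rest = rng.choice(pool, size=n_target - half, replace=False)
        sel = np.concatenate([first, rest])
    else:
        raise ValueError(f"unknown simplification method: {method!r}")
    sel = np.sort(sel)
    normals = None if cloud.normals is None else cloud.normals[sel]
    return PointCloud(cloud.points[sel], normals, cloud.ids[sel])
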