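"""Tangent-plane-distance non-rigid registration with local affine transforms.

The deformation model assigns one 3x4 affine transform per source point
(12n unknowns for n points).  The energy minimized is

    E(X) = E_d(X) + alpha * E_s(X)

with the tangent-plane (point-to-plane) distance term

    E_d(X) = sum_i ( w_i * (X_i [v_i; 1] - u_i) . n_i )^2

and the local-affine stiffness regularizer

    E_s(X) = || (M kron G) X ||_F^2,

where u_i is the closest target point to the deformed source point v_i,
n_i its unit normal, M the node-arc incidence matrix of the source
adjacency graph and G = diag(1, 1, 1, gamma) the stiffness matrix that
weights the rotation/skew rows of a transform difference against its
translation row.  Projecting residuals on the normal removes the penalty
on motion within the tangent plane, which is what lets sliding lung
motion escape the local minima a point-to-point distance creates.

The unknown is stored stacked as a 4n x 3 array X whose i-th 4x3 block is
the transpose of the i-th 3x4 affine; with the sparse n x 4n design
matrix D (row i = [v_i, 1] placed in columns 4i..4i+3), D @ X is the
deformed cloud.  E is minimized by gradient descent with correspondences
refreshed every outer iteration; an exact sparse solve of the fixed-
correspondence subproblem is available for stiffness-limit analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .geometry import (
    AdjacencyGraph,
    CorrespondenceSet,
    PointCloud,
    build_adjacency,
    closest_points,
    estimate_normals,
)

__all__ = [
    "AffineStack",
    "RegistrationConfig",
    "RegistrationResult",
    "build_design_matrix",
    "make_stiffness_operator",
    "distance_term",
    "regularization_term",
    "objective",
    "gradient",
    "gd_step",
    "armijo_gd_step",
    "apply_transform",
    "global_affine_fit",
    "register",
]


@dataclass
class AffineStack:
    """Stack of n local affine transforms as a (4n, 3) array.

    Block i (rows 4i..4i+3) is [A_i^T; t_i^T]: the first three rows hold
    the transpose of the linear part, the fourth row the translation, so
    that [v, 1] @ block = A v + t.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 3 or self.X.shape[0] % 4:
            raise ValueError("X must be a (4n, 3) array")

    @classmethod
    def identity(cls, n: int) -> "AffineStack":
        block = np.vstack([np.eye(3), np.zeros(3)])
        return cls(np.tile(block, (n, 1)))

    @property
    def n(self) -> int:
        return self.X.shape[0] // 4

    @property
    def blocks(self) -> np.ndarray:
        """View as (n, 4, 3) per-point blocks."""
        return self.X.reshape(self.n, 4, 3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        aug = np.column_stack([points, np.ones(len(points))])
        return np.einsum("ni,nij->nj", aug, self.blocks)


@dataclass
class RegistrationConfig:
    """Hyperparameters of both registration loops.

    alpha
        Regularization weight on coordinates normalized to a unit
        bounding-box diagonal (so it is scale-free).
    gamma
        Stiffness weight of the translation row in G = diag(1,1,1,gamma).
    step_length
        Gradient step; ``"auto"`` runs Armijo backtracking seeded at
        2 / L_hat with L_hat a power-iteration estimate of the Hessian
        norm, which guarantees monotone descent on fixed correspondences.
    max_outer / inner_steps
        Correspondence refreshes and gradient steps between refreshes.
    tol
        Relative energy-change threshold across an outer iteration.
    batch_fraction
        Fraction of points used for the distance term each inner step
        (1 = full batch; smaller values give a stochastic gradient,
        rescaled by 1/batch_fraction).
    solver
        ``"gd"`` for the gradient-descent loop; ``"direct"`` solves each
        fixed-correspondence subproblem exactly (sparse normal
        equations) — needed to traverse the stiff regime alpha -> inf,
        where plain gradient descent stalls.
    """

    alpha: float = 30.0
    gamma: float = 1.0
    step_length: float | str = "auto"
    max_outer: int = 300
    inner_steps: int = 30
    tol: float = 1e-6
    batch_fraction: float = 1.0
    seed: int = 0
    adjacency_k: int = 6
    normal_k: int = 12
    weighting: str = "uniform"
    solver: str = "gd"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if isinstance(self.step_length, str):
            if self.step_length != "auto":
                raise ValueError("step_length must be positive or 'auto'")
        elif self.step_length <= 0:
            raise ValueError("step_length must be positive or 'auto'")
        if not 0 < self.batch_fraction <= 1:
            raise ValueError("batch_fraction must lie in (0, 1]")
        if self.tol <= 0 or self.max_outer < 1 or self.inner_steps < 1:
            raise ValueError("tol, max_outer and inner_steps must be positive")
        if self.solver not in ("gd", "direct"):
            raise ValueError("solver must be 'gd' or 'direct'")


@dataclass
class RegistrationResult:
    affine_stack: AffineStack
    deformed_source: PointCloud
    energy_trace: np.ndarray  # (iters, 3): E, E_d, E_s (normalized coords)
    mre_trace: np.ndarray | None
    converged: bool
    iterations_run: int


def build_design_matrix(source: PointCloud) -> sparse.csr_matrix:
    """Sparse n x 4n matrix with row i = [x_i, y_i, z_i, 1] in columns 4i..4i+3."""
    n = source.n
    data = np.column_stack([source.points, np.ones(n)]).ravel()
    indices = (4 * np.arange(n)[:, None] + np.arange(4)[None, :]).ravel()
    indptr = 4 * np.arange(n + 1)
    return sparse.csr_matrix((data, indices, indptr), shape=(n, 4 * n))


def make_stiffness_operator(incidence: sparse.spmatrix, gamma: float) -> sparse.csr_matrix:
    """(M kron G) with G = diag(1, 1, 1, gamma): maps the 4n x 3 stack to
    per-edge stiffness-weighted block differences."""
    G = sparse.diags([1.0, 1.0, 1.0, gamma])
    return sparse.kron(incidence, G, format="csr")


def _distance_term(X: np.ndarray, D: sparse.spmatrix, corr: CorrespondenceSet) -> float:
    r = D @ X - corr.target_points
    s = corr.weights * np.einsum("ij,ij->i", r, corr.target_normals)
    return float(s @ s)


def distance_term(X: AffineStack, D: sparse.spmatrix, corr: CorrespondenceSet) -> float:
    """Tangent-plane distance term: sum_i (w_i (X_i [v_i;1] - u_i) . n_i)^2."""
    return _distance_term(X.X, D, corr)


def _regularization_term(X: np.ndarray, MG: sparse.spmatrix) -> float:
    R = MG @ X
    return float(np.sum(R * R))


def regularization_term(X: AffineStack, M: sparse.spmatrix | AdjacencyGraph,
                        gamma: float) -> float:
    """Stiffness term ||(M kron G) X||_F^2 over neighbouring-block differences."""
    incidence = M.incidence if isinstance(M, AdjacencyGraph) else M
    return _regularization_term(X.X, make_stiffness_operator(incidence, gamma))


def objective(X: AffineStack, D: sparse.spmatrix, corr: CorrespondenceSet,
              M: sparse.spmatrix | AdjacencyGraph, alpha: float,
              gamma: float) -> tuple[float, float, float]:
    """Composite energy: returns (E, E_d, E_s) with E = E_d + alpha * E_s."""
    ed = distance_term(X, D, corr)
    es = regularization_term(X, M, gamma)
    return ed + alpha * es, ed, es


def _gradient(X: np.ndarray, D: sparse.spmatrix, corr: CorrespondenceSet,
              MG: sparse.spmatrix, alpha: float) -> np.ndarray:
    r = D @ X - corr.target_points
    s = corr.weights * np.einsum("ij,ij->i", r, corr.target_normals)
    g = 2.0 * (D.T @ ((corr.weights * s)[:, None] * corr.target_normals))
    if alpha > 0:
        g += 2.0 * alpha * (MG.T @ (MG @ X))
    return g


def gradient(X: AffineStack, D: sparse.spmatrix, corr: CorrespondenceSet,
             M: sparse.spmatrix | AdjacencyGraph, alpha: float,
             gamma: float) -> np.ndarray:
    """Analytic gradient of the composite energy with respect to X.

    dE_d/dX = 2 D^T (w .* s .* N) with s_i = w_i (r_i . n_i) applied
    row-wise, and dE_s/dX = 2 alpha (M kron G)^T (M kron G) X.  Verified
    against central finite differences in the test suite.
    """
    incidence = M.incidence if isinstance(M, AdjacencyGraph) else M
    return _gradient(X.X, D, corr, make_stiffness_operator(incidence, gamma), alpha)


def gd_step(X: AffineStack, grad: np.ndarray, step_length: float) -> AffineStack:
    """One explicit gradient-descent update X_new = X_old - step * grad."""
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    if not np.isfinite(grad).all():
        raise ValueError("non-finite gradient")
    return AffineStack(X.X - step_length * grad)


def armijo_gd_step(X: AffineStack, grad: np.ndarray, energy_fn,
                   initial_step: float, c: float = 1e-4,
                   max_backtracks: int = 60):
    """Backtracking-line-search gradient step.

    Halves the step from ``initial_step`` until the Armijo condition
    ``E(X - t g) <= E(X) - c t ||g||^2`` holds; returns
    ``(X_new, E_new, t)`` with ``t = 0`` (and X unchanged) when no step
    makes progress, so the energy never increases.
    """
    if not np.isfinite(grad).all():
        raise ValueError("non-finite gradient")
    e0 = energy_fn(X.X)
    g2 = float(np.sum(grad * grad))
    if g2 == 0.0:
        return X, e0, 0.0
    t = initial_step
    for _ in range(max_backtracks):
        xn = X.X - t * grad
        en = energy_fn(xn)
        if en <= e0 - c * t * g2:
            return AffineStack(xn), en, t
        t *= 0.5
    return X, e0, 0.0


def apply_transform(X: AffineStack, source: PointCloud) -> PointCloud:
    """Deformed cloud Y with Y_i = X_i [v_i; 1] (normals are dropped)."""
    if X.n != source.n:
        raise ValueError("block count must equal the cloud size")
    return PointCloud(X.apply(source.points), ids=source.ids)


def _estimate_hessian_norm(D: sparse.spmatrix, corr: CorrespondenceSet,
                           MG: sparse.spmatrix, alpha: float,
                           rng: np.random.Generator, iters: int = 25) -> float:
    """Power-iteration estimate of the fixed-correspondence Hessian norm."""
    V = rng.standard_normal((D.shape[1], 3))
    V /= np.linalg.norm(V)
    lam = 1.0
    w2 = corr.weights**2
    for _ in range(iters):
        HV = 2.0 * (D.T @ ((w2 * np.einsum("ij,ij->i", D @ V, corr.target_normals))[:, None]
                           * corr.target_normals))
        if alpha > 0:
            HV += 2.0 * alpha * (MG.T @ (MG @ V))
        lam = float(np.sum(V * HV))
        nrm = np.linalg.norm(HV)
        if nrm == 0.0:
            break
        V = HV / nrm
    return max(lam, 1e-12)


def _solve_fixed_correspondences(D: sparse.spmatrix, corr: CorrespondenceSet,
                                 MG: sparse.spmatrix, alpha: float) -> np.ndarray:
    """Exact minimizer of the tangent-plane energy at fixed correspondences.

    E_d couples the three columns of X through the normals, so the
    normal equations are assembled on vec(X) (columns stacked): row i of
    the data matrix is w_i * (n_i kron d_i).
    """
    four_n = D.shape[1]
    W = corr.weights
    cols = [sparse.diags(W * corr.target_normals[:, c]) @ D for c in range(3)]
    A = sparse.hstack(cols, format="csr")  # n x 12n
    b = W * np.einsum("ij,ij->i", corr.target_points, corr.target_normals)
    K = (MG.T @ MG).tocsr()
    H = (A.T @ A + alpha * sparse.block_diag([K, K, K])).tocsc()
    x = splu(H).solve(A.T @ b)
    return np.ascontiguousarray(x.reshape(3, four_n).T)


def global_affine_fit(source: PointCloud, corr: CorrespondenceSet,
                      mode: str = "tangent") -> AffineStack:
    """Closed-form single-global-affine least-squares fit.

    ``mode='tangent'`` minimizes the tangent-plane distance term over one
    shared 3x4 affine; ``'p2p'`` minimizes the point-to-point term.  The
    result is returned as a uniform stack — the alpha -> infinity limit
    of both registration energies.
    """
    aug = np.column_stack([source.points, np.ones(source.n)])
    w = corr.weights
    if mode == "p2p":
        B, *_ = np.linalg.lstsq(w[:, None] * aug, w[:, None] * corr.target_points,
                                rcond=None)
    elif mode == "tangent":
        rows = np.concatenate(
            [corr.target_normals[:, c:c + 1] * aug for c in range(3)], axis=1)
        b = np.einsum("ij,ij->i", corr.target_points, corr.target_normals)
        x, *_ = np.linalg.lstsq(w[:, None] * rows, w * b, rcond=None)
        B = np.ascontiguousarray(x.reshape(3, 4).T)
    else:
        raise ValueError("mode must be 'tangent' or 'p2p'")
    return AffineStack(np.tile(B, (source.n, 1)))


def _normalization(source: PointCloud, target: PointCloud):
    """Centre and unit-bounding-box-diagonal scale over both clouds."""
    pts = np.vstack([source.points, target.points])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    centre = 0.5 * (lo + hi)
    scale = float(np.linalg.norm(hi - lo))
    if scale == 0.0:
        scale = 1.0
    return centre, scale


def _denormalize_stack(X: AffineStack, centre: np.ndarray, scale: float) -> AffineStack:
    """Map a stack acting on (p - c)/s coordinates back to millimetres.

    y = s * X((p - c)/s) + c gives A_mm = A, t_mm = c - A c + s t.
    """
    blocks = X.blocks.copy()
    A = blocks[:, :3, :]  # (n, 3, 3), each A_i^T
    t = blocks[:, 3, :]
    t_mm = centre[None, :] - np.einsum("j,nji->ni", centre, A) + scale * t
    blocks[:, 3, :] = t_mm
    return AffineStack(blocks.reshape(-1, 3))


def _prepare(source: PointCloud, target: PointCloud, config: RegistrationConfig):
    """Shared setup for both registration loops: normals, adjacency,
    normalization, design and stiffness operators, target KD-tree."""
    if target.normals is None:
        target = estimate_normals(target, k=config.normal_k)
    graph = build_adjacency(source, k=config.adjacency_k)
    if not graph.connected:
        raise ValueError(
            "source adjacency graph is disconnected; increase adjacency_k "
            "or supply a single connected surface"
        )
    if config.normalize:
        centre, scale = _normalization(source, target)
    else:
        centre, scale = np.zeros(3), 1.0
    src_n = PointCloud((source.points - centre) / scale, ids=source.ids)
    tgt_n = PointCloud((target.points - centre) / scale, normals=target.normals,
                       ids=target.ids)
    D = build_design_matrix(src_n)
    MG = make_stiffness_operator(graph.incidence, config.gamma)
    tree = cKDTree(tgt_n.points)
    return src_n, tgt_n, graph, D, MG, tree, centre, scale


def _mre_mm(X: np.ndarray, D: sparse.spmatrix, src_points_mm: np.ndarray,
            scale: float, centre: np.ndarray, truth_disp: np.ndarray) -> float:
    deformed_mm = scale * (D @ X) + centre
    est = deformed_mm - src_points_mm
    return float(np.mean(np.linalg.norm(truth_disp - est, axis=1)))


def register(source: PointCloud, target: PointCloud,
             config: RegistrationConfig | None = None,
             truth=None) -> RegistrationResult:
    """Tangent-plane-distance non-rigid registration.

    Outer loop: refresh closest-point correspondences on the deformed
    source.  Inner loop: ``inner_steps`` gradient-descent updates of the
    local affine stack (or one exact subproblem solve with
    ``solver='direct'``).  Stops when the relative energy change across
    an outer iteration falls below ``tol`` or after ``max_outer``
    refreshes.  X starts at the identity stack; coordinates are
    normalized internally, and the returned stack and deformed cloud are
    in millimetres.

    ``truth`` may be a :class:`~lungreg.synthetic.MotionField` (aligned
    with ``source``) to record a per-iteration mean-registration-error
    trace.
    """
    config = config or RegistrationConfig()
    src_n, tgt_n, graph, D, MG, tree, centre, scale = _prepare(source, target, config)
    n = src_n.n
    rng = np.random.default_rng(config.seed)
    X = AffineStack.identity(n)
    truth_disp = None if truth is None else np.asarray(truth.displacements, float)

    energy_trace: list[tuple[float, float, float]] = []
    mre_trace: list[float] = []
    e_prev = None
    converged = False
    grow_streak = 0
    auto = config.step_length == "auto"

    for it in range(config.max_outer):
        deformed = PointCloud(D @ X.X)
        corr = closest_points(deformed, tgt_n, weighting=config.weighting, tree=tree)

        def energy(x: np.ndarray) -> float:
            return _distance_term(x, D, corr) + config.alpha * _regularization_term(x, MG)

        if config.solver == "direct":
            X = AffineStack(_solve_fixed_correspondences(D, corr, MG, config.alpha))
            e = energy(X.X)
        else:
            if auto:
                lhat = _estimate_hessian_norm(D, corr, MG, config.alpha, rng)
                t0 = 2.0 / lhat
            for _ in range(config.inner_steps):
                if config.batch_fraction < 1.0:
                    m = max(1, int(round(config.batch_fraction * n)))
                    sub = rng.choice(n, size=m, replace=False)
                    sub_corr = CorrespondenceSet(
                        corr.target_points[sub], corr.target_normals[sub],
                        corr.weights[sub], corr.distances[sub])
                    Dsub = D[sub]
                    g = _gradient(X.X, Dsub, sub_corr, MG, 0.0) / config.batch_fraction
                    if config.alpha > 0:
                        g += 2.0 * config.alpha * (MG.T @ (MG @ X.X))
                else:
                    g = _gradient(X.X, D, corr, MG, config.alpha)
                if auto:
                    X, e, _ = armijo_gd_step(X, g, energy, t0)
                else:
                    X = gd_step(X, g, config.step_length)
                    e = energy(X.X)

        ed = _distance_term(X.X, D, corr)
        es = _regularization_term(X.X, MG)
        energy_trace.append((ed + config.alpha * es, ed, es))
        e = ed + config.alpha * es
        if truth_disp is not None:
            mre_trace.append(_mre_mm(X.X, D, source.points, scale, centre, truth_disp))

        if not np.isfinite(e) and not auto and config.solver == "gd":
            raise RuntimeError(
                "energy diverged (non-finite) under the fixed step length; "
                "try step_length='auto'"
            )
        if e_prev is not None:
            if not auto and config.solver == "gd" and e > e_prev:
                grow_streak += 1
                if grow_streak >= 5:
                    raise RuntimeError(
                        "energy increased for 5 consecutive outer iterations "
                        "with a fixed step; try step_length='auto'"
                    )
            else:
                grow_streak = 0
            if abs(e_prev - e) <= config.tol * max(abs(e_prev), 1e-300):
                converged = True
                e_prev = e
                break
        e_prev = e

    X_mm = _denormalize_stack(X, centre, scale)
    return RegistrationResult(
        affine_stack=X_mm,
        deformed_source=apply_transform(X_mm, source),
        energy_trace=np.asarray(energy_trace),
        mre_trace=np.asarray(mre_trace) if mre_trace else None,
        converged=converged,
        iterations_run=len(energy_trace),
    )
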