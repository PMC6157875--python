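"""Synthetic lung-like surfaces and ground-truth respiratory motion fields.

Real inputs to the registration pipeline are lung surfaces segmented from
4DCT volumes at end-inspiration and end-expiration.  This module
generates structurally analogous data so every stage is testable without
any imaging data: a closed half-ellipsoid shell with a flattened medial
face stands in for the segmented lung, a diaphragm-driven displacement
field (large cranial motion at the base decaying exponentially towards
the apex) stands in for breathing motion, and an added tangential
component in the lateral bands emulates the sliding of the lung against
the chest wall.  Decimating source and target independently with
disjoint ids reproduces the loss of point correspondence that image
segmentation entails; corresponding pairs apply the same decimation to
both phases.

The functional forms are stand-ins chosen for qualitative fidelity, not
biomechanical realism; every constant is a named argument.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PointCloud, estimate_normals, surface_variation

__all__ = [
    "MotionField",
    "SyntheticPairSpec",
    "make_lung_surface",
    "make_motion_field",
    "make_registration_pair",
]


@dataclass
class MotionField:
    """Per-point displacement vectors (mm), aligned with a cloud by id."""

    displacements: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.displacements = np.ascontiguousarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 3:
            raise ValueError("displacements must be an (n, 3) array")
        if not np.isfinite(self.displacements).all():
            raise ValueError("displacements contain non-finite values")
        if self.ids is not None:
            self.ids = np.ascontiguousarray(self.ids, dtype=np.int64)
            if self.ids.shape != (self.displacements.shape[0],):
                raise ValueError("ids must be a length-n integer vector")
            if np.unique(self.ids).size != self.ids.size:
                raise ValueError("ids must be unique")

    @property
    def n(self) -> int:
        return self.displacements.shape[0]


@dataclass
class SyntheticPairSpec:
    """Recipe for one registration experiment.

    Defaults follow the clinical experiment scale: the dense segmented
    surface has ~20000 points, the source is decimated to 4000 and the
    target to 8000 points.  ``corresponding=True`` decimates source and
    target jointly so that the clouds are in one-to-one correspondence;
    otherwise they are decimated independently with disjoint ids.
    """

    n_dense: int = 20000
    n_source: int = 4000
    n_target: int = 8000
    corresponding: bool = False
    field_kind: str = "sliding"  # "diaphragm" | "sliding" | "global_affine"
    amplitude: float = 5.0  # mm
    seed: int = 0
    semi_axes: tuple[float, float, float] = (60.0, 90.0, 120.0)
    sampling: str = "random"  # "random" | "curvature"

    def __post_init__(self) -> None:
        if self.n_source > self.n_dense or self.n_target > self.n_dense:
            raise ValueError("decimated sizes must not exceed n_dense")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.corresponding and self.n_source + self.n_target > self.n_dense:
            raise ValueError(
                "disjoint decimation requires n_source + n_target <= n_dense"
            )
        if self.field_kind not in ("diaphragm", "sliding", "global_affine"):
            raise ValueError(f"unknown field kind: {self.field_kind!r}")
        if self.sampling not in ("random", "curvature"):
            raise ValueError(f"unknown sampling rule: {self.sampling!r}")


def make_lung_surface(
    n_dense: int,
    seed: int = 0,
    semi_axes: tuple[float, float, float] = (60.0, 90.0, 120.0),
    flatten_frac: float = 0.55,
) -> PointCloud:
    """Quasi-uniform sample of a lung-like closed shell.

    Points are drawn area-uniformly (by rejection) on an ellipsoid with
    the given semi-axes (mm); the medial face is flattened by projecting
    points with ``x > flatten_frac * a`` onto that plane, which gives the
    shell the flat medial side of a left lung while the ellipsoid bottom
    provides the rounded basal cap.  Deterministic under ``seed``; ids
    are 0..n-1.
    """
    if n_dense < 500:
        raise ValueError("n_dense must be >= 500")
    a, b, c = semi_axes
    rng = np.random.default_rng(seed)
    pts = np.empty((n_dense, 3))
    got = 0
    # area element of the sphere->ellipsoid map, relative to its maximum
    sigma_max = max(1.0 / a, 1.0 / b, 1.0 / c)
    while got < n_dense:
        m = 2 * (n_dense - got) + 64
        u = rng.standard_normal((m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        sigma = np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
        accept = rng.random(m) < sigma / sigma_max
        cand = u[accept] * np.array([a, b, c])
        take = min(len(cand), n_dense - got)
        pts[got:got + take] = cand[:take]
        got += take
    cut = flatten_frac * a
    pts[pts[:, 0] > cut, 0] = cut
    return PointCloud(pts, ids=np.arange(n_dense))


def make_motion_field(
    cloud: PointCloud,
    kind: str,
    amplitude: float,
    seed: int = 0,
    lateral_band: float = 0.3,
) -> MotionField:
    """Ground-truth displacement field on a cloud.

    ``"diaphragm"``: purely cranial motion ``(0, 0, A exp(-(z - z_min)/tau))``
    with ``tau`` one third of the cloud's z-extent — amplitude A at the
    base decaying to ~A e^-3 at the apex, emulating diaphragm-driven
    breathing.

    ``"sliding"``: the diaphragm field plus a tangential component of
    magnitude A/2 in the lateral bands (points with ``|n_z| <
    lateral_band``), directed along the unit projection of the cranial
    axis onto the local tangent plane, so that the added motion satisfies
    ``u . n = 0`` exactly — the sliding of the lung surface against the
    chest wall.  Requires normals on the cloud.

    ``"global_affine"``: a fixed small affine map (rotation 2 degrees
    about y, isotropic scale 1.05, translation (2, 1, -3) mm) minus the
    identity — a deformation the local-affine model can represent
    exactly with a uniform stack.
    """
    z = cloud.points[:, 2]
    if kind == "diaphragm" or kind == "sliding":
        z_min = z.min()
        extent = z.max() - z_min
        tau = extent / 3.0 if extent > 0 else 1.0
        disp = np.zeros_like(cloud.points)
        disp[:, 2] = amplitude * np.exp(-(z - z_min) / tau)
        if kind == "sliding":
            if cloud.normals is None:
                raise ValueError("sliding field requires normals on the cloud")
            nrm = cloud.normals
            band = np.abs(nrm[:, 2]) < lateral_band
            zhat = np.array([0.0, 0.0, 1.0])
            tang = zhat[None, :] - nrm * nrm[:, 2:3]
            tlen = np.linalg.norm(tang, axis=1, keepdims=True)
            tang = np.divide(tang, tlen, out=np.zeros_like(tang), where=tlen > 0)
            disp[band] += 0.5 * amplitude * tang[band]
        return MotionField(disp, ids=cloud.ids)
    if kind == "global_affine":
        th = np.deg2rad(2.0)
        rot = np.array([
            [np.cos(th), 0.0, np.sin(th)],
            [0.0, 1.0, 0.0],
            [-np.sin(th), 0.0, np.cos(th)],
        ])
        A = 1.05 * rot if amplitude > 0 else np.eye(3)
        t = np.array([2.0, 1.0, -3.0]) * (amplitude / 5.0)
        disp = cloud.points @ A.T + t - cloud.points
        return MotionField(disp, ids=cloud.ids)
    raise ValueError(f"unknown field kind: {kind!r}")


def _weighted_disjoint_split(rng, n, n_source, n_target, weights=None):
    """Disjoint index sets for independent source/target decimation."""
    if weights is None:
        perm = rng.permutation(n)
        return np.sort(perm[:n_source]), np.sort(perm[n_source:n_source + n_target])
    p = weights / weights.sum()
    src = rng.choice(n, size=n_source, replace=False, p=p)
    pool = np.setdiff1d(np.arange(n), src)
    wp = weights[pool]
    tgt = pool[rng.choice(len(pool), size=n_target, replace=False, p=wp / wp.sum())]
    return np.sort(src), np.sort(tgt)


def make_registration_pair(spec: SyntheticPairSpec):
    """Generate a (source, target-with-normals, truth) triple.

    Dense phase-one cloud F is built and displaced by the ground-truth
    field to give dense phase-two cloud R; target normals are always
    computed on the dense R (the dense cloud gives more accurate normals
    than a decimated one) and carried to the decimated target by id.
    Corresponding mode decimates F and moves the selected points by the
    truth field; non-corresponding mode decimates F and R independently
    with disjoint ids.  The truth field is the ground-truth displacement
    restricted to the source points, and the whole construction is
    bit-reproducible under ``spec``.
    """
    dense = make_lung_surface(spec.n_dense, seed=spec.seed, semi_axes=spec.semi_axes)
    dense = estimate_normals(dense, k=12)
    fld = make_motion_field(dense, spec.field_kind, spec.amplitude, seed=spec.seed)
    dense_moved = PointCloud(dense.points + fld.displacements, ids=dense.ids)
    dense_moved = estimate_normals(dense_moved, k=12)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    weights = None
    if spec.sampling == "curvature":
        weights = surface_variation(dense, k=12) + 0.05

    if spec.corresponding:
        if weights is None:
            sel = np.sort(rng.choice(spec.n_dense, size=spec.n_source, replace=False))
        else:
            p = weights / weights.sum()
            sel = np.sort(rng.choice(spec.n_dense, size=spec.n_source,
                                     replace=False, p=p))
        source = PointCloud(dense.points[sel], ids=sel)
        target = PointCloud(dense_moved.points[sel],
                            normals=dense_moved.normals[sel], ids=sel)
        truth = MotionField(fld.displacements[sel], ids=sel)
    else:
        s_idx, t_idx = _weighted_disjoint_split(
            rng, spec.n_dense, spec.n_source, spec.n_target, weights)
        source = PointCloud(dense.points[s_idx], ids=s_idx)
        target = PointCloud(dense_moved.points[t_idx],
                            normals=dense_moved.normals[t_idx], ids=t_idx)
        truth = MotionField(fld.displacements[s_idx], ids=s_idx)
    return source, target, truth
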