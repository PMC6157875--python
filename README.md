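# lungreg

Non-rigid point-cloud registration for lung-surface motion estimation,
built around a **tangent-plane (point-to-plane) distance** with a local
affine deformation model.

## The problem

Respiration-correlated CT (4DCT) delivers one static 3-D volume per
breathing phase; estimating how the lung surface moves *between* phases
(e.g. end-inspiration to end-expiration) is a precondition for tumour
tracking and dose planning in radiotherapy. Surfaces segmented from two
phases come as point clouds that are **not** in one-to-one
correspondence, and the lung **slides** tangentially along the chest
wall — the regime in which classical point-to-point ICP registration
falls into local minima, because it penalizes exactly the tangential
motion that the data cannot constrain.

## The method

Each source point `v_i` carries its own 3×4 affine transform `X_i`
(12n unknowns).  Writing `u_i` for the closest target point to the
deformed `v_i` and `n_i` for its unit normal, the energy is

```
E(X) = Σ_i ( w_i (X_i [v_i;1] − u_i) · n_i )²  +  α ‖(M ⊗ G) X‖²_F
```

* the first term is the squared **distance to the tangent plane** of the
  matched target point — residuals *within* the tangent plane are free,
  so sliding motion is not penalized;
* the second is a **stiffness regularizer**: `M` is the node-arc
  incidence matrix of a symmetric k-NN graph over the source cloud and
  `G = diag(1,1,1,γ)` weights rotation/skew against translation in each
  neighbouring-transform difference.

`E` is minimized by gradient descent (`X ← X − ΔL ∂E/∂X`, Armijo
backtracking step) with closest-point correspondences refreshed every
outer iteration.  The damped steps double as a trust region: solving
each correspondence subproblem exactly makes the cloud drift tangentially,
while small descent steps converge stably.

For comparison the package ships the classical **point-to-point
non-rigid ICP** baseline (`Σ w_i² ‖X_i [v_i;1] − u_i‖²` with the same
regularizer), solved analytically per iteration by a sparse linear
solve, plus a synthetic lung-surface/motion simulator, the
mean-registration-error (MRE) metric

```
MRE = (1/n) Σ_i | T_true,i − T_est,i |   [mm]
```

and readers/writers for PLY / OBJ / XYZ clouds and 6-column motion-field
tables.

## Worked example

Simulate a lung-like pair with diaphragm-plus-sliding motion (5 mm
amplitude, source and target decimated independently so no point
correspondences exist), then run both methods:

```sh
lungreg simulate --out sim --n-dense 8000 --n-source 1500 \
    --n-target 3000 --field-kind sliding --amplitude 5 --seed 0
lungreg compare --source sim/source.ply --target sim/target.ply \
    --truth sim/truth.tsv --out cmp
```

prints

```
mre_nricp_p2p_mm: 1.59758363
mre_tangent_plane_mm: 1.29224391
improvement_pct: 19.1125973
```

i.e. starting from a mean true motion of ~3 mm, the point-to-point
baseline leaves a 1.60 mm mean error while the tangent-plane method
reaches 1.29 mm — a 19% accuracy gain, driven by the lateral sliding
bands where only the tangent-plane term leaves the motion free for the
regularizer to resolve.  `cmp/` also contains per-point error tables and
per-iteration MRE traces for both methods: the analytic baseline is
stable within ~10 outer iterations, the gradient method keeps improving
for hundreds.

The same workflow runs on your own data: `lungreg register --source
ei.ply --target ee.ply --out result` accepts PLY/OBJ/XYZ clouds in
millimetres (target normals are estimated if absent) and writes the
deformed source, the estimated motion field and the resolved
configuration.

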