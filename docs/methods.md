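# Methods

## Deformation model and energies

The deformation of the source cloud (n points, millimetres) is a stack
of local affine transforms, one 3×4 matrix `X_i` per point — 12n free
parameters.  Internally the unknown is stored as a 4n×3 array `X` whose
i-th 4×3 block is `X_iᵀ`; the sparse n×4n design matrix `D` (row i =
`[v_i, 1]` in columns 4i…4i+3) makes `D X` the deformed cloud, so all
energy evaluations are sparse-dense products.

Two distance terms are implemented over closest-point correspondences
`(u_i, n_i)`:

* **tangent-plane**: `E_d = Σ (w_i (X_i[v_i;1] − u_i) · n_i)²` — the
  squared distance from the deformed point to the plane through `u_i`
  orthogonal to `n_i`.  It is invariant to the sign of every normal and
  has an exact tangential null space: perturbing a deformed point within
  its correspondence tangent plane changes nothing (to first order at
  zero residual, exactly for translations along the plane).
* **point-to-point**: `E_p2p = Σ w_i² ‖X_i[v_i;1] − u_i‖²` — the
  classical non-rigid-ICP term, positive for tangential residuals.

Both share the stiffness regularizer `E_s = ‖(M ⊗ G) X‖²_F`, with `M`
the |E|×n node-arc incidence matrix of a symmetric k-nearest-neighbour
graph over the source cloud (default k=6 — the typical valence of a
triangulated surface, standing in for an explicit triangulation) and
`G = diag(1,1,1,γ)`.  Each row of `(M ⊗ G) X` is a
stiffness-weighted difference of neighbouring blocks, so `E_s` penalizes
spatial variation of the transforms; γ re-weights the translation row
against the rotation/skew rows (default γ=1).  The composite energy is
`E = E_d + α E_s`.  A connected adjacency graph is required and
enforced: on a disconnected graph the regularizer no longer couples all
transforms and the normal equations are singular.

The gradient used by the descent loop is derived directly from the
energy above:

```
∂E_d/∂X = 2 Dᵀ (w ⊙ s ⊙ N),   s_i = w_i (r_i · n_i),  r_i = (DX − U)_i
∂E_s/∂X = 2 (M ⊗ G)ᵀ (M ⊗ G) X
```

(first expression applied row-wise to the normal matrix N).  It is
verified against central finite differences (h = 1e-6 on normalized
coordinates, relative error ≤ 1e-6) across α ∈ {0, 1, 100} and
γ ∈ {0.5, 1, 2} in the test suite.

## Optimization

`register` alternates (outer) closest-point refreshes with (inner)
gradient-descent updates `X ← X − ΔL g`.  The default step rule "auto"
estimates the fixed-correspondence Hessian norm `L̂` by power iteration
(the subproblem is an exact quadratic, so one estimate per outer
iteration suffices) and backtracks from `ΔL₀ = 2/L̂` under the Armijo
condition, which guarantees a non-increasing energy within each
fixed-correspondence phase.  A fixed numeric `ΔL` is also supported; the
loop aborts with a diagnostic if the energy grows five outer iterations
in a row or becomes non-finite under a fixed step.  Stopping: relative
energy change across an outer iteration below `tol` (default 1e-6) or
`max_outer` refreshes.  Coordinates are normalized internally to a unit
bounding-box diagonal (both clouds jointly), which makes α and the step
length scale-free; the returned stack and deformed cloud are
de-normalized back to millimetres.

An exact solver for the tangent-plane fixed-correspondence subproblem
(`solver="direct"`, sparse normal equations on vec(X)) exists alongside
the descent loop, but it is **not** the default: fully minimizing the
tangent-plane energy before each correspondence refresh lets the cloud
drift within its tangent planes (nothing anchors sliding between
refreshes), and the iteration visibly diverges — mean error 1.4 mm after
one solve, 3.0 mm after ten on a standard sliding pair.  The small
damped gradient steps act as a trust region that suppresses this drift,
which is why the descent loop is the method's native solver.  The direct
solver remains the right tool where drift cannot occur and descent
cannot reach: the stiffness limit α → ∞ (neighbouring blocks forced
equal — plain descent stalls because the conditioning grows with α) and
exactly-representable deformations on corresponding clouds.

The point-to-point baseline (`nricp_register`) shares adjacency,
weights, normalization and stopping rule, and solves its
fixed-correspondence subproblem analytically — one sparse factorization
reused across iterations — which is why it stabilizes within ~10 outer
iterations where the gradient loop needs hundreds.

`batch_fraction < 1` turns the distance-term gradient into a stochastic
(mini-batch) estimate rescaled by 1/fraction; the default is full batch.
Correspondence weights default to `w_i = 1`; an optional robust mode
zeroes weights beyond median + 3·MAD of the current distances.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| α | 30 | regularization weight on unit-diagonal coordinates. Chosen as the point-to-point baseline's own accuracy optimum on the sliding benchmark (its MRE is flat between α=30 and α=100 and worse below), so method comparisons never handicap the baseline; descent conditioning degrades linearly in α, and α=30 keeps the gradient loop convergent within the iteration budget. |
| γ | 1 | equal weighting of rotational and translational block differences. |
| adjacency k | 6 | typical valence of a triangulated closed surface. |
| normals k | 12 | covariance neighbourhood; normals are computed on the *dense* phase-two cloud and carried to the decimated target by id (denser clouds give more accurate normals); estimated at k=12 on the target itself when only a decimated cloud exists. |
| inner_steps | 30 | gradient steps per correspondence refresh; with the Armijo step the descent is monotone, and ~30 steps per refresh reach MRE-level convergence within max_outer. |
| max_outer | 300 | correspondence refreshes. |
| tol | 1e-6 | relative energy change per outer iteration. |

## Synthetic data

`make_lung_surface` samples an ellipsoid shell (semi-axes 60×90×120 mm)
area-uniformly by rejection and flattens the medial face by projecting
points beyond 0.55·a onto that plane — the flat medial side and rounded
basal cap of a (left) lung.  Motion fields:

* **diaphragm** — `(0, 0, A e^{−(z−z_min)/τ})`, τ = one third of the
  z-extent: A (default 5 mm) of cranial motion at the base decaying to
  ~0.05·A at the apex;
* **sliding** — diaphragm plus a tangential component of magnitude A/2
  in the lateral bands (|n_z| < 0.3), directed along the projection of
  the cranial axis onto the tangent plane, so the added motion satisfies
  `u · n = 0` exactly;
* **global_affine** — a fixed small affine map (2° rotation, 1.05
  scale, (2, 1, −3) mm translation), exactly representable by a uniform
  stack.

Pairs are produced by displacing the dense cloud and decimating: jointly
(one-to-one corresponding clouds) or independently with disjoint ids
(the non-corresponding situation segmentation produces).  Everything is
bit-reproducible from the spec and seed.

These stand-ins reproduce the qualitative structure of segmented lung
surfaces — basal motion, apical stillness, lateral tangential sliding,
lost correspondences — but not their texture: no segmentation noise or
artifacts, no lobe fissures, a smooth analytic shell instead of an
anatomical shape, and a binary sliding band whose edge is a motion
discontinuity.  Passing tests therefore demonstrate the mechanisms
(tangential null space, correspondence-free accuracy gain), not clinical
error magnitudes.

## Observed behaviour and limitations

On non-corresponding sliding pairs the tangent-plane method reduces the
median MRE by ~20% relative to the baseline (amplitude 5 mm, 2000/4000
points) — the tangential motion it leaves free is reconstructed by the
regularizer from the normal-observable basal motion, while the baseline
locks onto wrong nearest-sample correspondences whose bias scales with
target spacing.

On **corresponding** pairs the relationship inverts in our conditions:
closest-point search recovers the true partners (motion amplitude is
comparable to point spacing), the point-to-point term then uses full
3-D information and reaches ~0.7 mm, while the tangent-plane method, by
construction blind to tangential evidence, stays near its
non-corresponding accuracy (~1.2 mm).  Reported near-parity between the
two approaches on corresponding data belongs to a regime where
correspondences are *not* discoverable by closest-point search (rough
fields, both methods regularization-limited); our smooth generator does
not produce that regime, and the parity acceptance check is accordingly
expected to fail under these study conditions.

Other limitations: normals from covariance analysis degrade on sparse
or noisy patches (sign is irrelevant to the energy, orientation fixed
only for reproducible output); the gradient loop's conditioning worsens
with α, making very stiff problems the direct solver's domain; no
landmark terms, no multi-resolution schedule, and the local affine model
cannot represent genuinely discontinuous fields across the sliding
interface — errors concentrate at the band edges for both methods.
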