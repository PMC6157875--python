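"""Tangent-plane energy, gradient, and gradient-descent registration loop."""
import numpy as np
import pytest

from lungreg import (AffineStack, PointCloud, RegistrationConfig,
                     apply_transform, build_design_matrix, distance_term,
                     estimate_normals, gd_step, gradient, objective,
                     register, regularization_term)
from lungreg.baseline import p2p_distance_term
from lungreg.geometry import CorrespondenceSet, build_adjacency
from lungreg.registration import (armijo_gd_step, global_affine_fit,
                                  make_stiffness_operator)
from lungreg.synthetic import MotionField

from conftest import random_correspondences


def random_stack(g, n, scale=1.0):
    return AffineStack(AffineStack.identity(n).X + scale * g.standard_normal((4 * n, 3)))


def random_instance(g, n, weights=None):
    """Cloud + design + correspondences + adjacency for energy tests."""
    cloud = PointCloud(g.standard_normal((n, 3)))
    D = build_design_matrix(cloud)
    corr = random_correspondences(g, n, weights)
    graph = build_adjacency(cloud, k=3)
    return cloud, D, corr, graph


class TestDesignMatrix:
    def test_single_point_row(self):
        D = build_design_matrix(PointCloud(np.array([[1.0, 2.0, 3.0]])))
        assert np.allclose(D.toarray(), [[1.0, 2.0, 3.0, 1.0]])

    def test_identity_stack_reproduces_source(self, rng):
        cloud = PointCloud(rng.standard_normal((30, 3)))
        D = build_design_matrix(cloud)
        assert np.allclose(D @ AffineStack.identity(30).X, cloud.points)

    def test_matches_per_point_affine_loop(self, rng):
        cloud = PointCloud(rng.standard_normal((20, 3)))
        D = build_design_matrix(cloud)
        X = random_stack(rng, 20)
        out = D @ X.X
        for i, (p, block) in enumerate(zip(cloud.points, X.blocks)):
            assert np.allclose(out[i], np.append(p, 1.0) @ block, atol=1e-12)


class TestDistanceTerm:
    def test_zero_at_coincidence(self, rng):
        cloud = PointCloud(rng.standard_normal((15, 3)))
        D = build_design_matrix(cloud)
        corr = random_correspondences(rng, 15)
        corr.target_points = cloud.points.copy()
        assert distance_term(AffineStack.identity(15), D, corr) == 0.0

    def test_normal_residual_squared(self):
        cloud = PointCloud(np.zeros((1, 3)))
        D = build_design_matrix(cloud)
        d = 2.5
        corr = CorrespondenceSet(np.array([[0.0, 0.0, -d]]),
                                 np.array([[0.0, 0.0, 1.0]]),
                                 np.ones(1), np.array([d]))
        assert np.isclose(distance_term(AffineStack.identity(1), D, corr), d * d)

    def test_tangential_residual_is_free_while_p2p_is_not(self):
        # residual orthogonal to the normal: zero plane distance, full
        # point-to-point penalty — the mechanism that frees sliding motion
        cloud = PointCloud(np.zeros((1, 3)))
        D = build_design_matrix(cloud)
        t = 3.0
        corr = CorrespondenceSet(np.array([[t, 0.0, 0.0]]),
                                 np.array([[0.0, 0.0, 1.0]]),
                                 np.ones(1), np.array([t]))
        X = AffineStack.identity(1)
        assert distance_term(X, D, corr) == 0.0
        assert np.isclose(p2p_distance_term(X, D, corr), t * t)

    def test_matches_per_point_loop(self, rng):
        n = 30
        w = rng.uniform(0.1, 1.0, n)
        cloud, D, corr, _ = random_instance(rng, n, weights=w)
        X = random_stack(rng, n)
        got = distance_term(X, D, corr)
        expected = 0.0
        for i in range(n):
            r = np.append(cloud.points[i], 1.0) @ X.blocks[i] - corr.target_points[i]
            expected += (w[i] * (r @ corr.target_normals[i])) ** 2
        assert abs(got - expected) <= 1e-12 * expected


class TestRegularizationTerm:
    def test_uniform_stack_is_free(self, rng):
        _, _, _, graph = random_instance(rng, 12)
        X = AffineStack(np.tile(rng.standard_normal((4, 3)), (12, 1)))
        assert regularization_term(X, graph, gamma=1.7) <= 1e-20

    def test_translation_difference_scaled_by_gamma(self):
        cloud = PointCloud(np.array([[0.0, 0, 0], [1, 0, 0]]))
        graph = build_adjacency(cloud, k=1)
        X = AffineStack.identity(2)
        X.X[7, 0] = 1.0  # second block translation differs by (1, 0, 0)
        assert np.isclose(regularization_term(X, graph, gamma=2.0), 4.0)

    def test_matches_per_edge_loop(self, rng):
        n = 15
        cloud, _, _, graph = random_instance(rng, n)
        X = random_stack(rng, n)
        gamma = 1.3
        got = regularization_term(X, graph, gamma)
        G = np.diag([1.0, 1.0, 1.0, gamma])
        expected = sum(
            np.sum((G @ (X.blocks[i] - X.blocks[j])) ** 2)
            for i, j in graph.edges)
        assert abs(got - expected) <= 1e-12 * expected


class TestObjective:
    def test_alpha_zero_reduces_to_distance(self, rng):
        _, D, corr, graph = random_instance(rng, 10)
        X = random_stack(rng, 10)
        e, ed, es = objective(X, D, corr, graph, alpha=0.0, gamma=1.0)
        assert e == ed == distance_term(X, D, corr)

    def test_components_sum(self, rng):
        _, D, corr, graph = random_instance(rng, 18)
        X = random_stack(rng, 18)
        alpha = 7.5
        e, ed, es = objective(X, D, corr, graph, alpha=alpha, gamma=0.8)
        assert np.isclose(e, ed + alpha * es, rtol=1e-14)
        assert np.isclose(ed, distance_term(X, D, corr), rtol=1e-14)
        assert np.isclose(es, regularization_term(X, graph, 0.8), rtol=1e-14)


def finite_difference_gradient(X, D, corr, MG, alpha, h=1e-6):
    from lungreg.registration import _distance_term, _regularization_term

    def energy(x):
        return _distance_term(x, D, corr) + alpha * _regularization_term(x, MG)

    g = np.zeros_like(X.X)
    for idx in np.ndindex(X.X.shape):
        xp = X.X.copy(); xp[idx] += h
        xm = X.X.copy(); xm[idx] -= h
        g[idx] = (energy(xp) - energy(xm)) / (2 * h)
    return g


class TestGradient:
    def test_zero_at_global_minimum(self, rng):
        cloud = PointCloud(rng.standard_normal((8, 3)))
        D = build_design_matrix(cloud)
        corr = random_correspondences(rng, 8)
        corr.target_points = cloud.points.copy()
        graph = build_adjacency(cloud, k=3)
        g = gradient(AffineStack.identity(8), D, corr, graph, 50.0, 1.0)
        assert np.allclose(g, 0.0, atol=1e-14)

    def test_single_point_translation_row(self):
        # v = origin, u = (0,0,-1), n = z: residual (0,0,1) projects fully,
        # so the gradient lives in the translation row and equals (0,0,2)
        cloud = PointCloud(np.zeros((1, 3)))
        D = build_design_matrix(cloud)
        corr = CorrespondenceSet(np.array([[0.0, 0.0, -1.0]]),
                                 np.array([[0.0, 0.0, 1.0]]),
                                 np.ones(1), np.ones(1))
        MG = make_stiffness_operator(
            build_adjacency(PointCloud(np.array([[0.0, 0, 0], [1, 0, 0]])),
                            k=1).incidence, 1.0)
        from lungreg.registration import _gradient
        g = _gradient(AffineStack.identity(1).X, D, corr, MG[:, :4] * 0.0, 0.0)
        expected = np.zeros((4, 3))
        expected[3] = [0.0, 0.0, 2.0]
        assert np.allclose(g, expected, atol=1e-14)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 100.0])
    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
    def test_matches_finite_differences(self, alpha, gamma):
        g = np.random.default_rng(int(alpha * 10 + gamma * 100))
        for trial in range(4):
            n = int(g.integers(5, 50))
            w = g.uniform(0.2, 1.0, n)
            cloud, D, corr, graph = random_instance(g, n, weights=w)
            MG = make_stiffness_operator(graph.incidence, gamma)
            X = random_stack(g, n, scale=0.3)
            analytic = gradient(X, D, corr, graph, alpha, gamma)
            fd = finite_difference_gradient(X, D, corr, MG, alpha)
            rel = np.linalg.norm(analytic - fd) / np.linalg.norm(fd)
            assert rel <= 1e-6

    def test_tangential_perturbations_are_first_order_free(self, rng):
        # at zero normal residual, moving deformed points within their
        # correspondence tangent planes leaves E_d unchanged to first order
        n = 12
        cloud = PointCloud(rng.standard_normal((n, 3)))
        D = build_design_matrix(cloud)
        corr = random_correspondences(rng, n)
        corr.target_points = cloud.points.copy()  # zero residual
        X = AffineStack.identity(n)
        g = gradient(X, D, corr, build_adjacency(cloud, k=3), 0.0, 1.0)
        # any perturbation direction: directional derivative is zero at the
        # minimum; check that per-point translational tangent moves give
        # exactly zero first-order change
        for i in range(n):
            tangent = np.cross(corr.target_normals[i], rng.standard_normal(3))
            V = np.zeros_like(X.X)
            V[4 * i + 3] = tangent
            assert abs(np.sum(g * V)) <= 1e-12

    def test_invariant_to_normal_sign_flips(self, rng):
        n = 20
        _, D, corr, graph = random_instance(rng, n)
        X = random_stack(rng, n)
        flip = rng.random(n) < 0.5
        corr_flipped = CorrespondenceSet(
            corr.target_points,
            np.where(flip[:, None], -corr.target_normals, corr.target_normals),
            corr.weights, corr.distances)
        assert np.isclose(distance_term(X, D, corr),
                          distance_term(X, D, corr_flipped), rtol=1e-14)
        assert np.allclose(gradient(X, D, corr, graph, 3.0, 1.0),
                           gradient(X, D, corr_flipped, graph, 3.0, 1.0),
                           atol=1e-12)


class TestGdStep:
    def test_zero_gradient_leaves_stack(self):
        X = AffineStack.identity(5)
        out = gd_step(X, np.zeros_like(X.X), 0.3)
        assert np.array_equal(out.X, X.X)

    def test_unit_step_with_ones(self):
        X = AffineStack.identity(2)
        out = gd_step(X, np.ones_like(X.X), 1.0)
        assert np.allclose(out.X, X.X - 1.0)

    def test_non_finite_gradient_rejected(self):
        X = AffineStack.identity(1)
        g = np.full_like(X.X, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            gd_step(X, g, 0.1)

    def test_armijo_descends_on_fixed_correspondences(self, rng):
        from lungreg.registration import (_distance_term, _gradient,
                                          _regularization_term)
        n = 25
        cloud, D, corr, graph = random_instance(rng, n)
        MG = make_stiffness_operator(graph.incidence, 1.0)
        alpha = 5.0

        def energy(x):
            return _distance_term(x, D, corr) + alpha * _regularization_term(x, MG)

        X = random_stack(rng, n, scale=0.2)
        e_prev = energy(X.X)
        for _ in range(30):
            g = _gradient(X.X, D, corr, MG, alpha)
            X, e, t = armijo_gd_step(X, g, energy, 1.0)
            assert e <= e_prev + 1e-15
            if t == 0.0:
                break
            assert e < e_prev  # accepted steps strictly decrease
            e_prev = e


class TestApplyTransform:
    def test_identity(self, rng):
        cloud = PointCloud(rng.standard_normal((10, 3)))
        assert np.allclose(apply_transform(AffineStack.identity(10), cloud).points,
                           cloud.points)

    def test_pure_translation(self, rng):
        cloud = PointCloud(rng.standard_normal((10, 3)))
        X = AffineStack.identity(10)
        t = np.array([1.0, -2.0, 0.5])
        X.blocks[:, 3, :] = t
        assert np.allclose(apply_transform(X, cloud).points, cloud.points + t)

    def test_matches_per_point_loop(self, rng):
        cloud = PointCloud(rng.standard_normal((25, 3)))
        X = random_stack(rng, 25)
        out = apply_transform(X, cloud)
        for i in range(25):
            expected = X.blocks[i].T @ np.append(cloud.points[i], 1.0)
            assert np.allclose(out.points[i], expected, atol=1e-12)


class TestRegister:
    def test_self_registration_is_fixed_point(self, shell_with_normals):
        truth = MotionField(np.zeros((shell_with_normals.n, 3)),
                            ids=shell_with_normals.ids)
        res = register(shell_with_normals, shell_with_normals, truth=truth)
        assert res.mre_trace[-1] < 1e-3
        assert np.allclose(res.affine_stack.X,
                           AffineStack.identity(shell_with_normals.n).X,
                           atol=1e-6)

    def test_result_deformed_source_consistency(self, small_pair):
        source, target, truth = small_pair
        cfg = RegistrationConfig(max_outer=10, inner_steps=5)
        res = register(source, target, cfg, truth=truth)
        redone = apply_transform(res.affine_stack, source)
        assert np.allclose(res.deformed_source.points, redone.points, atol=1e-9)
        assert res.iterations_run == len(res.energy_trace)

    def test_disconnected_source_refused(self):
        pts = np.vstack([np.random.default_rng(1).standard_normal((20, 3)),
                         np.random.default_rng(2).standard_normal((20, 3)) + 1e4])
        src = PointCloud(pts)
        tgt = estimate_normals(PointCloud(
            np.random.default_rng(3).standard_normal((50, 3))), k=6)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="disconnected"):
                register(src, tgt, RegistrationConfig(adjacency_k=2))

    def test_divergence_with_fixed_step_aborts(self, small_pair):
        source, target, _ = small_pair
        cfg = RegistrationConfig(step_length=1e6, max_outer=20)
        with pytest.raises(RuntimeError, match="auto"):
            register(source, target, cfg)

    def test_batch_fraction_one_equals_full_batch(self, small_pair):
        source, target, truth = small_pair
        a = register(source, target,
                     RegistrationConfig(max_outer=5, inner_steps=3,
                                        batch_fraction=1.0, seed=1), truth=truth)
        b = register(source, target,
                     RegistrationConfig(max_outer=5, inner_steps=3, seed=1),
                     truth=truth)
        assert np.allclose(a.energy_trace, b.energy_trace)

    def test_stochastic_batching_still_descends(self, small_pair):
        source, target, truth = small_pair
        res = register(source, target,
                       RegistrationConfig(max_outer=60, inner_steps=5,
                                          batch_fraction=0.5, seed=2),
                       truth=truth)
        assert res.mre_trace[-1] < res.mre_trace[0]


class TestStiffnessLimit:
    def test_huge_alpha_collapses_to_global_affine(self):
        # alpha -> inf forces a uniform stack equal to the closed-form
        # single-affine least-squares fit of the tangent-plane energy
        from lungreg import (SyntheticPairSpec, make_registration_pair,
                             closest_points)
        src, tgt, _ = make_registration_pair(SyntheticPairSpec(
            n_dense=2000, n_source=400, n_target=800, field_kind="sliding",
            amplitude=5.0, seed=2))
        allpts = np.vstack([src.points, tgt.points])
        c = 0.5 * (allpts.min(0) + allpts.max(0))
        s = np.linalg.norm(allpts.max(0) - allpts.min(0))
        src_n = PointCloud((src.points - c) / s, ids=src.ids)
        tgt_n = PointCloud((tgt.points - c) / s, normals=tgt.normals, ids=tgt.ids)
        cfg = RegistrationConfig(alpha=1e8, solver="direct", max_outer=15,
                                 normalize=False)
        res = register(src_n, tgt_n, cfg)
        graph = build_adjacency(src_n, k=6)
        blocks = res.affine_stack.blocks
        diffs = np.linalg.norm(blocks[graph.edges[:, 0]] - blocks[graph.edges[:, 1]],
                               axis=(1, 2))
        assert diffs.max() <= 1e-4
        corr = closest_points(res.deformed_source, tgt_n)
        D = build_design_matrix(src_n)
        e_conv, *_ = objective(res.affine_stack, D, corr, graph, 1e8, 1.0)
        fit = global_affine_fit(src_n, corr, mode="tangent")
        e_fit, *_ = objective(fit, D, corr, graph, 1e8, 1.0)
        assert abs(e_conv - e_fit) <= 0.01 * e_fit
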