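"""MVEE geometry, adaptive exploration, ellipsoid sampling, union volumes."""

import numpy as np
import pytest

from kinens.exceptions import KinensError
from kinens.hyperspace import (Ellipsoid, ExplorationConfig, estimate_volume,
                               mebs, mvee, oeamc, unit_ball_volume)


def cfg(seed=0, **kw):
    defaults = dict(seed=seed, batch_size=150, max_iterations=4000,
                    mebs_batch=80, mebs_max_iter=12, mebs_local_perturbations=15)
    defaults.update(kw)
    return ExplorationConfig(**defaults)


class TestMVEE:
    def test_single_point_degenerate_floor(self):
        ell = mvee(np.array([[1.0, 2.0]]))
        assert ell.contains(np.array([[1.0, 2.0]]))[0]
        assert ell.volume > 0

    def test_square_corners_give_circle(self):
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        ell = mvee(pts, tolerance=1e-7)
        np.testing.assert_allclose(ell.center, 0.0, atol=1e-6)
        assert ell.volume == pytest.approx(2 * np.pi, rel=1e-4)

    def test_contains_all_points_always(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.normal(size=(rng.integers(2, 40), rng.integers(1, 5)))
            ell = mvee(pts)
            assert np.all(ell.contains(pts))

    def test_volume_near_optimal_vs_independent_solver(self):
        """Khachiyan result within tolerance of a direct dual solve via
        scipy.optimize (log-det maximization over point weights)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(5)
        P = rng.normal(size=(30, 3))
        tol = 1e-4
        ell = mvee(P, tolerance=tol)
        assert np.all(ell.contains(P))

        # independent oracle: maximize log det sum u_i q_i q_i^T over simplex
        Q = np.hstack([P, np.ones((30, 1))])

        def neg_logdet(u):
            X = Q.T @ np.diag(u) @ Q
            sign, ld = np.linalg.slogdet(X)
            return -ld if sign > 0 else 1e9

        cons = ({"type": "eq", "fun": lambda u: u.sum() - 1.0},)
        res = minimize(neg_logdet, np.full(30, 1 / 30), bounds=[(0, 1)] * 30,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 300, "ftol": 1e-12})
        u = res.x / res.x.sum()
        c = P.T @ u
        cov = P.T @ np.diag(u) @ P - np.outer(c, c)
        E = np.linalg.inv(cov) / 3
        oracle = Ellipsoid(c, E)
        worst = float(np.max(oracle.mahalanobis_sq(P)))
        if worst > 1:
            oracle = Ellipsoid(c, E / worst)
        # both solvers are iterative; agree to within 1%
        assert ell.volume <= oracle.volume * 1.01

    def test_degenerate_collinear_points_regularized(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        ell = mvee(pts)
        assert np.all(ell.contains(pts))
        assert ell.volume > 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mvee(np.empty((0, 2)))


class TestEllipsoid:
    def test_uniform_sampling_stays_inside(self):
        rng = np.random.default_rng(1)
        ell = Ellipsoid(np.array([1.0, -2.0]),
                        np.array([[2.0, 0.3], [0.3, 0.5]]))
        pts = ell.sample(500, rng)
        assert np.all(ell.contains(pts, tol=1e-12))

    def test_scaled_volume_relation(self):
        ell = Ellipsoid(np.zeros(3), np.diag([1.0, 4.0, 0.25]))
        assert ell.scaled(2.0).volume == pytest.approx(8 * ell.volume)

    def test_ball_volume(self):
        ball = Ellipsoid(np.zeros(3), np.eye(3) / 4.0)  # radius 2
        assert ball.volume == pytest.approx(32 * np.pi / 3)
        assert unit_ball_volume(2) == pytest.approx(np.pi)


class TestOEAMC:
    def test_box_region_recovered(self):
        pred = lambda x: bool(np.all(x >= 0) and np.all(x <= 1))  # noqa: E731
        vs = oeamc(np.array([0.5, 0.5]), pred,
                   (np.zeros(2), np.full(2, 10.0)), cfg(seed=3))
        assert len(vs) > 50
        assert np.all(vs.points >= 0) and np.all(vs.points <= 1)
        # an ellipsoid cover of the unit square cannot be smaller than the
        # square and a single enclosing ellipse has area pi/2, so at
        # convergence the summed cover volume sits in [~1, ~pi/2]
        final_volume = vs.log[-1]["volume"]
        assert 0.7 <= final_volume <= 1.05 * np.pi / 2

    def test_never_viable_returns_start_with_warning(self):
        calls = {"n": 0}

        def pred(x):
            calls["n"] += 1
            return calls["n"] == 1  # only the start check passes

        vs = oeamc(np.array([5.0, 5.0]), pred,
                   (np.zeros(2), np.full(2, 10.0)),
                   cfg(seed=1, max_iterations=600))
        assert len(vs) == 1
        assert not vs.converged

    def test_nonviable_start_raises(self):
        with pytest.raises(KinensError):
            oeamc(np.array([5.0]), lambda x: False,
                  (np.zeros(1), np.ones(1) * 10), cfg(seed=0))

    def test_two_disc_multimodal_coverage(self):
        """Out-of-equilibrium jumps reach a second disconnected viable disc
        in most seeded runs."""
        c1, c2 = np.array([2.0, 2.0]), np.array([8.0, 8.0])

        def pred(x):
            return bool(np.linalg.norm(x - c1) < 1.0 or
                        np.linalg.norm(x - c2) < 1.0)

        hits = 0
        for seed in range(10):
            vs = oeamc(c1.copy(), pred, (np.zeros(2), np.full(2, 10.0)),
                       cfg(seed=seed, max_iterations=6000,
                           jump_probability=0.15, convergence_tol=1e-3,
                           converged_checks=3))
            if np.any(np.linalg.norm(vs.points - c2, axis=1) < 1.0):
                hits += 1
        assert hits >= 8

    def test_bit_reproducible_under_seed(self):
        pred = lambda x: bool(np.all(x >= 0) and np.all(x <= 1))  # noqa: E731
        a = oeamc(np.array([0.5, 0.5]), pred,
                  (np.zeros(2), np.full(2, 10.0)), cfg(seed=9))
        b = oeamc(np.array([0.5, 0.5]), pred,
                  (np.zeros(2), np.full(2, 10.0)), cfg(seed=9))
        np.testing.assert_array_equal(a.points, b.points)


class TestMEBS:
    def test_ellipsoidal_region_volume_recovered(self):
        """Convex ellipsoidal viable region: cover volume within 20%."""
        E = np.diag([1 / 4.0, 1.0])  # semi-axes 2 and 1, area 2*pi
        region = Ellipsoid(np.array([5.0, 5.0]), E)
        pred = lambda x: bool(region.contains(x[None])[0])  # noqa: E731
        box = (np.zeros(2), np.full(2, 10.0))
        coarse = oeamc(np.array([5.0, 5.0]), pred, box, cfg(seed=2))
        fine, cover = mebs(coarse, pred, cfg(seed=4), bounds_box=box)
        vol, se = estimate_volume(cover, 20000, seed=5, box=box)
        assert vol == pytest.approx(region.volume, rel=0.20)

    def test_every_returned_point_is_viable(self):
        pred = lambda x: bool(np.all(x >= 0) and np.all(x <= 1))  # noqa: E731
        box = (np.zeros(2), np.full(2, 10.0))
        coarse = oeamc(np.array([0.5, 0.5]), pred, box, cfg(seed=6))
        fine, cover = mebs(coarse, pred, cfg(seed=7), bounds_box=box)
        assert all(pred(p) for p in fine.points)

    def test_duplicate_coarse_points_terminate(self):
        pred = lambda x: bool(np.all(np.abs(x - 5) < 1))  # noqa: E731
        from kinens.hyperspace import ViablePointSet
        dup = ViablePointSet(np.array([[5.0, 5.0]] * 7))
        fine, cover = mebs(dup, pred, cfg(seed=8, mebs_max_iter=5),
                           bounds_box=(np.zeros(2), np.full(2, 10.0)))
        assert len(cover) >= 1  # processed once, no hang


class TestEstimateVolume:
    def test_single_ball(self):
        ball = Ellipsoid(np.zeros(3), np.eye(3) / 4.0)
        vol, se = estimate_volume([ball], 20000, seed=1)
        assert abs(vol - 32 * np.pi / 3) <= 3 * max(se, 1e-9)

    def test_disjoint_balls_additive(self):
        b1 = Ellipsoid(np.zeros(3), np.eye(3))
        b2 = Ellipsoid(np.array([5.0, 0, 0]), np.eye(3))
        vol, se = estimate_volume([b1, b2], 20000, seed=2)
        assert abs(vol - 2 * 4 * np.pi / 3) <= 3 * max(se, 1e-9)

    def test_lens_overlap_closed_form(self):
        """Two unit balls at distance 1: union = 9*pi/4 (lens formula)."""
        b1 = Ellipsoid(np.zeros(3), np.eye(3))
        b2 = Ellipsoid(np.array([1.0, 0, 0]), np.eye(3))
        vol, se = estimate_volume([b1, b2], 40000, seed=3)
        assert abs(vol - 9 * np.pi / 4) <= 3 * max(se, 1e-9)

    def test_standard_error_shrinks_like_sqrt_n(self):
        b1 = Ellipsoid(np.zeros(2), np.eye(2))
        b2 = Ellipsoid(np.array([1.0, 0.0]), np.eye(2))
        _, se_small = estimate_volume([b1, b2], 2000, seed=4)
        _, se_big = estimate_volume([b1, b2], 32000, seed=4)
        assert se_big == pytest.approx(se_small / 4.0, rel=0.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_volume([Ellipsoid(np.zeros(2), np.eye(2))], 50, seed=0)

    def test_box_clipping_reduces_volume(self):
        ball = Ellipsoid(np.zeros(2), np.eye(2))  # area pi
        half = (np.array([0.0, -2.0]), np.array([2.0, 2.0]))  # keep x >= 0
        vol, se = estimate_volume([ball], 20000, seed=5, box=half)
        assert vol == pytest.approx(np.pi / 2, rel=0.05)
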