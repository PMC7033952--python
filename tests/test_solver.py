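from types import SimpleNamespace

import numpy as np
import pytest

from _oracles import full_objective_oracle, numeric_grad
from conftest import make_dataset, random_groups
from gflsgl.data import GroupStructure, LongitudinalDataset
from gflsgl.penalties import objective
from gflsgl.solver import GFLSGL, FitResult, SolverConfig, fit, predict
from gflsgl.taskgraph import TaskGraph


def masked_lstsq(ds):
    obs = ds.mask.astype(bool)
    return np.column_stack([
        np.linalg.pinv(ds.X[obs[:, t]]) @ ds.Y[obs[:, t], t]
        for t in range(ds.k)])


TIGHT = dict(max_iter=6000, tol_primal=1e-9, tol_obj=1e-13)


class TestThetaUpdate:
    def test_single_task_identity_design_closed_form(self, rng):
        # X = I, one task with D = [1], Phi = [1]: first sweep solves
        # (X'X + 2 rho I) theta = X'y from the all-zero start
        y = rng.normal(size=(2, 1))
        ds = LongitudinalDataset(np.eye(2), y, np.ones((2, 1), dtype=np.int8))
        tg = SimpleNamespace(k=1, D=np.array([[1.0]]), Phi=np.array([[1.0]]),
                             sigma=1.0)
        model = GFLSGL(ds, GroupStructure.singletons(2), tg)
        st = model._run_admm(SolverConfig(max_iter=1))
        np.testing.assert_allclose(st.theta, y / 3.0, atol=1e-12)

    def test_first_sweep_is_stationary_point_of_quadratic(self, rng):
        ds = make_dataset(rng, n=15, p=4, k=3)
        tg = TaskGraph(3, sigma=1.0)
        model = GFLSGL(ds, GroupStructure.singletons(4), tg)
        rho = 1.3
        st = model._run_admm(SolverConfig(rho=rho, max_iter=1))
        # from the zero start Q = Gamma = U = V = 0, so the Jacobi sweep
        # minimizes, per column t with the other columns frozen at zero,
        # 1/2||mask_t (y_t - X v)||^2 + rho/2 ||v||^2 + rho/2 ||T(v) D||^2
        obs = ds.mask.astype(bool)
        for t in range(ds.k):
            def quad_col(v, t=t):
                T = np.zeros((ds.p, ds.k))
                T[:, t] = v.ravel()
                R = np.where(obs, ds.Y - ds.X @ T, 0.0)
                return (0.5 * np.sum(R ** 2) + 0.5 * rho * np.sum(T ** 2)
                        + 0.5 * rho * np.sum((T @ tg.D) ** 2))

            g = numeric_grad(quad_col, st.theta[:, t].copy(), eps=1e-6)
            assert np.linalg.norm(g) < 1e-6 * max(1, np.linalg.norm(st.theta))

    def test_mask_equals_explicit_row_deletion(self, rng):
        # with lambda's 0 the solution per task is least squares on the
        # task's observed rows: the masked normal equations must agree
        # with explicitly deleting rows
        ds = make_dataset(rng, n=30, p=5, k=3, miss=0.3)
        tg = TaskGraph(3, sigma=1.0)
        res = GFLSGL(ds, GroupStructure.singletons(5), tg).fit(
            config=SolverConfig(**TIGHT))
        np.testing.assert_allclose(res.theta, masked_lstsq(ds), atol=1e-6)


class TestFit:
    def test_unpenalized_recovers_masked_least_squares(self, rng):
        ds = make_dataset(rng, n=40, p=6, k=4, miss=0.2)
        tg = TaskGraph(4)
        res = fit(ds, GroupStructure.singletons(6), tg, SolverConfig(**TIGHT))
        expected = masked_lstsq(ds)
        rel = np.linalg.norm(res.theta - expected) / np.linalg.norm(expected)
        assert rel < 1e-4

    def test_lasso_reduction_matches_coordinate_descent(self, rng):
        from sklearn.linear_model import Lasso

        ds = make_dataset(rng, n=50, p=8, k=3, miss=0.0)
        tg = TaskGraph(3)
        lam = 2.0
        res = fit(ds, GroupStructure.singletons(8), tg,
                  SolverConfig(lambda1=lam, **TIGHT))
        for t in range(ds.k):
            sk = Lasso(alpha=lam / ds.n, fit_intercept=False, tol=1e-14,
                       max_iter=200000).fit(ds.X, ds.Y[:, t])

            def obj_t(w):
                return 0.5 * np.sum((ds.Y[:, t] - ds.X @ w) ** 2) \
                    + lam * np.abs(w).sum()

            assert obj_t(res.theta[:, t]) <= obj_t(sk.coef_) + 1e-5

    def test_matches_generic_convex_solver(self, rng):
        ds = make_dataset(rng, n=30, p=12, k=4, miss=0.15)
        gs = GroupStructure([np.arange(3 * l, 3 * l + 3) for l in range(4)])
        tg = TaskGraph(4, sigma=1.0)
        lam = (0.5, 1.0, 1.0)
        res = fit(ds, gs, tg, SolverConfig(*lam, **TIGHT))
        obs = ds.mask.astype(bool)
        opt, _ = full_objective_oracle(ds.X, np.where(obs, ds.Y, 0.0),
                                       ds.mask, tg.D, gs.groups, gs.weights,
                                       *lam)
        ours = objective(res.theta, ds, gs, tg, *lam)
        assert (ours - opt) / opt < 1e-3

    def test_gauss_seidel_agrees_with_jacobi(self, rng):
        ds = make_dataset(rng, n=30, p=6, k=3)
        gs = random_groups(rng, 6, 2)
        tg = TaskGraph(3)
        lam = dict(lambda1=0.2, lambda2=0.5, lambda3=0.5)
        a = GFLSGL(ds, gs, tg).fit(config=SolverConfig(**lam, **TIGHT))
        b = GFLSGL(ds, gs, tg).fit(config=SolverConfig(
            **lam, theta_update="gauss_seidel", **TIGHT))
        assert abs(a.objective - b.objective) / a.objective < 1e-6

    def test_max_iter_reached_reports_not_converged(self, rng):
        ds = make_dataset(rng, n=20, p=4, k=2)
        res = GFLSGL(ds).fit(lambda1=1.0, max_iter=2, tol_primal=1e-14,
                             tol_obj=1e-16)
        assert isinstance(res, FitResult)
        assert not res.converged and res.n_iter == 2

    def test_reported_theta_has_exact_zeros(self, rng):
        ds = make_dataset(rng, n=40, p=10, k=3,
                          theta=np.vstack([np.ones((2, 3)),
                                           np.zeros((8, 3))]))
        res = GFLSGL(ds).fit(lambda1=20.0, max_iter=3000)
        assert np.any(res.theta == 0.0)
        # smooth iterate and sparse copy agree at convergence
        assert np.linalg.norm(res.theta - res.theta_smooth) <= \
            10 * res.config.tol_primal * max(1, np.linalg.norm(res.theta))


class TestFitProperties:
    def test_objective_and_residuals_converge(self, rng):
        # objective sequence settles and both primal residuals vanish
        for seed in range(3):
            ds = make_dataset(np.random.default_rng(seed), n=30, p=8, k=3)
            gs = random_groups(np.random.default_rng(seed + 100), 8, 3)
            res = GFLSGL(ds, gs).fit(lambda1=0.3, lambda2=0.5, lambda3=0.5,
                                     max_iter=5000, tol_primal=1e-8,
                                     tol_obj=1e-12)
            assert res.state.r_split_history[-1] < 1e-6
            assert res.state.r_fused_history[-1] < 1e-6
            objs = np.array(res.state.objective_history)
            tail = objs[-10:]
            assert np.abs(tail - tail[-1]).max() / abs(tail[-1]) < 1e-8

    def test_feature_permutation_equivariance(self, rng):
        ds = make_dataset(rng, n=30, p=6, k=3)
        gs = GroupStructure([np.array([0, 1, 2]), np.array([3, 4, 5])])
        lam = dict(lambda1=0.3, lambda2=0.6, lambda3=0.4)
        res = GFLSGL(ds, gs).fit(**lam, **TIGHT)
        perm = rng.permutation(6)
        ds_p = LongitudinalDataset(ds.X[:, perm], ds.Y.copy(), ds.mask.copy())
        inv = np.argsort(perm)
        gs_p = GroupStructure([np.sort(inv[g]) for g in gs.groups])
        res_p = GFLSGL(ds_p, gs_p).fit(**lam, **TIGHT)
        np.testing.assert_allclose(res_p.theta, res.theta[perm, :], atol=1e-6)

    def test_l1_ladder_monotone_sparsity(self, rng):
        ds = make_dataset(rng, n=40, p=10, k=3)
        zeros = []
        for lam1 in (0.1, 1.0, 5.0, 20.0, 100.0):
            res = GFLSGL(ds).fit(lambda1=lam1, max_iter=3000)
            zeros.append(np.sum(res.theta == 0.0))
        assert all(a <= b for a, b in zip(zeros, zeros[1:]))

    def test_l3_ladder_shrinks_temporal_deviations(self, rng):
        ds = make_dataset(rng, n=40, p=8, k=4)
        gs = random_groups(rng, 8, 2)
        tg = TaskGraph(4)
        norms = []
        for lam3 in (0.0, 1.0, 10.0, 100.0):
            res = GFLSGL(ds, gs, tg).fit(lambda3=lam3, **TIGHT)
            norms.append(np.linalg.norm(res.theta_smooth @ tg.D))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_masked_cells_never_influence_fit(self, rng):
        ds = make_dataset(rng, n=30, p=5, k=3, miss=0.3)
        res1 = GFLSGL(ds).fit(lambda1=0.5, lambda2=0.5, max_iter=500)
        ds2 = LongitudinalDataset(ds.X.copy(), ds.Y.copy(), ds.mask.copy())
        # plant junk in the masked cells behind the validator's back:
        # the fit must be bit-identical
        ds2.Y[~ds2.mask.astype(bool)] = 1e6
        res2 = GFLSGL(ds2).fit(lambda1=0.5, lambda2=0.5, max_iter=500)
        np.testing.assert_array_equal(res1.theta, res2.theta)
        np.testing.assert_array_equal(res1.state.objective_history,
                                      res2.state.objective_history)


class TestPredict:
    def test_zero_coefficients_zero_prediction(self):
        assert np.all(predict(np.zeros((3, 2)), np.ones((4, 3))) == 0)

    def test_identity_design_returns_theta_rows(self, rng):
        theta = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(predict(theta, np.eye(4)), theta)

    def test_matches_matrix_product(self, rng):
        theta = rng.normal(size=(5, 2))
        X = rng.normal(size=(7, 5))
        np.testing.assert_allclose(predict(theta, X), X @ theta)

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            predict(np.zeros((3, 2)), np.ones((4, 2)))


class TestResults:
    def test_summary_mentions_key_facts(self, rng):
        ds = make_dataset(rng, n=25, p=6, k=3)
        res = GFLSGL(ds).fit(lambda1=1.0, max_iter=1000)
        text = res.summary()
        for token in ("lambda1=1", "iterations", "objective",
                      "nonzero coefficients"):
            assert token in text

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(lambda1=-1)
        with pytest.raises(ValueError):
            SolverConfig(rho=0)
        with pytest.raises(ValueError):
            SolverConfig(theta_update="cyclic")
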