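"""The ALM solver: block updates, convergence, and the SVT baseline."""

import dataclasses

import numpy as np
import pytest
import scipy.linalg

from dlgrmc import HyperParams, fit, objective, plain_matrix_completion, svt
from dlgrmc.graph import build_laplacian, laplacian_pair
from dlgrmc.solver import (
    ALMState,
    augmented_lagrangian,
    nuclear_norm,
    stationarity_residual,
    update_J,
    update_multipliers,
    update_X,
    update_Z,
)


def random_laplacians(rng, d, t):
    def W(n):
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        return w

    DS, TS = W(d), W(t)
    return DS, TS, laplacian_pair(DS, TS)


class TestSVT:
    def test_zero_threshold_is_identity(self, rng):
        Y = rng.normal(size=(5, 3))
        assert np.allclose(svt(Y, 0.0), Y)

    def test_diagonal_shrinkage(self):
        Y = np.diag([3.0, 1.0])
        assert np.allclose(svt(Y, 2.0), np.diag([1.0, 0.0]))

    def test_proximal_optimality_against_perturbations(self, rng):
        # svt(Y, tau) minimizes tau*||J||_* + 0.5*||J - Y||_F^2
        Y = rng.normal(size=(6, 4))
        tau = 0.7
        J = svt(Y, tau)

        def prox_obj(Jc):
            return tau * nuclear_norm(Jc) + 0.5 * np.sum((Jc - Y) ** 2)

        base = prox_obj(J)
        for _ in range(1000):
            pert = J + rng.normal(scale=rng.uniform(1e-3, 0.5), size=J.shape)
            assert prox_obj(pert) >= base - 1e-10


class TestObjective:
    def test_zero_everything(self, rng):
        _, _, laps = random_laplacians(rng, 4, 3)
        hp = HyperParams()
        assert objective(np.zeros((4, 3)), np.zeros((4, 3)), laps, hp) == 0.0

    def test_only_fidelity_term(self, rng):
        # X = 0: beta * ||−A||_F^2 = beta * (number of ones)
        A = np.zeros((4, 3))
        A[[0, 1, 2], [0, 1, 2]] = 1
        DS, TS = np.eye(4), np.eye(3)
        laps = laplacian_pair(DS, TS)
        hp = HyperParams(beta=2.5)
        assert objective(np.zeros((4, 3)), A, laps, hp) == pytest.approx(2.5 * 3)

    def test_term_by_term_oracle(self, rng):
        DS, TS, laps = random_laplacians(rng, 5, 4)
        X = rng.normal(size=(5, 4))
        A = (rng.uniform(size=(5, 4)) < 0.4).astype(float)
        hp = HyperParams(alpha=0.3, beta=1.7, lam=0.9)
        nuc = scipy.linalg.svdvals(X).sum()
        tik = hp.alpha * np.sum(X**2)
        fid = hp.beta * np.sum((A * X - A) ** 2)
        L_d, L_t = build_laplacian(DS), build_laplacian(TS)
        smooth = hp.lam * (np.trace(X.T @ L_d @ X) + np.trace(X @ L_t @ X.T))
        assert objective(X, A, laps, hp) == pytest.approx(nuc + tik + fid + smooth)

    def test_nan_rejected(self, rng):
        _, _, laps = random_laplacians(rng, 3, 3)
        X = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            objective(X, np.zeros((3, 3)), laps, HyperParams())


class TestUpdateJ:
    def test_large_penalty_limit_recovers_X(self, rng):
        X = rng.normal(size=(5, 4))
        J = update_J(X, np.zeros_like(X), 1e8)
        assert np.allclose(J, X, atol=1e-6)

    def test_zero_input_gives_zero(self):
        X = np.ones((3, 2))
        Y1 = -X  # X + Y1/mu1 = 0 at mu1 = 1
        assert np.allclose(update_J(X, Y1, 1.0), 0.0)


class TestUpdateZ:
    def test_beta_zero_collapses_to_shifted_X(self, rng):
        X, Y2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        Z = update_Z(X, Y2, 2.0, np.zeros((4, 3)), beta=0.0)
        assert np.allclose(Z, X + Y2 / 2.0)

    def test_observed_ones_are_stationary(self):
        X = np.ones((2, 2))
        A = np.ones((2, 2))
        Z = update_Z(X, np.zeros_like(X), 3.0, A, beta=1.5)
        assert np.allclose(Z, 1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_elementwise_matches_dense_linear_system(self, trial):
        # literal stationarity system: R vec(Z) = vec(C) with
        # R = 2*beta*diag(vec A) + mu2*I, C = 2*beta*(A∘A) + mu2*X + Y2
        rng = np.random.default_rng(trial)
        d, t = 4, 3
        X = rng.normal(size=(d, t))
        Y2 = rng.normal(size=(d, t))
        A = (rng.uniform(size=(d, t)) < 0.5).astype(float)
        beta, mu2 = rng.uniform(0.1, 5.0), rng.uniform(0.1, 5.0)
        R = 2 * beta * np.diag(A.ravel()) + mu2 * np.eye(d * t)
        C = 2 * beta * (A * A) + mu2 * X + Y2
        expected = np.linalg.solve(R, C.ravel()).reshape(d, t)
        assert np.allclose(update_Z(X, Y2, mu2, A, beta), expected, atol=1e-10)


class TestUpdateX:
    def test_lambda_zero_decouples_elementwise(self, rng):
        DS, TS, laps = random_laplacians(rng, 4, 3)
        hp = HyperParams(alpha=0.5, lam=0.0)
        J, Z = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        Y1, Y2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        mu1, mu2 = 1.3, 0.7
        X = update_X(J, Z, Y1, Y2, mu1, mu2, laps, hp)
        expected = (mu1 * J + mu2 * Z - Y1 - Y2) / (2 * hp.alpha + mu1 + mu2)
        assert np.allclose(X, expected)

    def test_consistent_blocks_fixed_point(self, rng):
        _, _, laps = random_laplacians(rng, 4, 3)
        hp = HyperParams(alpha=0.0, lam=0.0)
        J = rng.normal(size=(4, 3))
        X = update_X(J, J, np.zeros_like(J), np.zeros_like(J), 1.0, 1.0, laps, hp)
        assert np.allclose(X, J)

    @pytest.mark.parametrize("trial", range(20))
    def test_stationarity_residual_small(self, trial):
        rng = np.random.default_rng(100 + trial)
        d, t = 6, 5
        DS, TS, laps = random_laplacians(rng, d, t)
        hp = HyperParams(
            alpha=rng.uniform(0, 2), lam=rng.uniform(0, 2), beta=1.0
        )
        J, Z = rng.normal(size=(d, t)), rng.normal(size=(d, t))
        Y1, Y2 = rng.normal(size=(d, t)), rng.normal(size=(d, t))
        mu1, mu2 = rng.uniform(0.1, 10), rng.uniform(0.1, 10)
        X = update_X(J, Z, Y1, Y2, mu1, mu2, laps, hp)
        res = stationarity_residual(X, J, Z, Y1, Y2, mu1, mu2, laps, hp)
        B = mu1 * J + mu2 * Z - Y1 - Y2
        assert res <= 1e-8 * (1 + np.max(np.abs(B)))

    def test_matches_scipy_sylvester(self, rng):
        # independent cross-check of the eigenbasis solve
        d, t = 5, 4
        DS, TS, laps = random_laplacians(rng, d, t)
        hp = HyperParams(alpha=0.4, lam=1.3)
        J, Z = rng.normal(size=(d, t)), rng.normal(size=(d, t))
        Y1, Y2 = rng.normal(size=(d, t)), rng.normal(size=(d, t))
        mu1, mu2 = 0.8, 1.1
        X = update_X(J, Z, Y1, Y2, mu1, mu2, laps, hp)
        Aco = (2 * hp.alpha + mu1 + mu2) * np.eye(d) + 2 * hp.lam * laps.L_d
        Bco = 2 * hp.lam * laps.L_t
        Q = mu1 * J + mu2 * Z - Y1 - Y2
        assert np.allclose(X, scipy.linalg.solve_sylvester(Aco, Bco, Q), atol=1e-8)


class TestMultipliers:
    def _state(self, rng, d=3, t=2):
        return ALMState(
            X=rng.normal(size=(d, t)),
            J=rng.normal(size=(d, t)),
            Z=rng.normal(size=(d, t)),
            Y1=rng.normal(size=(d, t)),
            Y2=rng.normal(size=(d, t)),
            mu1=0.5,
            mu2=0.9,
        )

    def test_feasible_point_leaves_multipliers_unchanged(self, rng):
        st = self._state(rng)
        st.J = st.X.copy()
        st.Z = st.X.copy()
        Y1, Y2, _, _ = update_multipliers(st, HyperParams())
        assert np.allclose(Y1, st.Y1) and np.allclose(Y2, st.Y2)

    def test_rho_one_keeps_penalties_constant(self, rng):
        st = self._state(rng)
        _, _, mu1, mu2 = update_multipliers(st, HyperParams(rho=1.0))
        assert (mu1, mu2) == (0.5, 0.9)

    def test_gradient_ascent_recomputation(self, rng):
        st = self._state(rng)
        hp = HyperParams(rho=1.3, mu_max=10.0)
        Y1, Y2, mu1, mu2 = update_multipliers(st, hp)
        assert np.allclose(Y1, st.Y1 + st.mu1 * (st.X - st.J))
        assert np.allclose(Y2, st.Y2 + st.mu2 * (st.X - st.Z))
        assert mu1 == pytest.approx(0.5 * 1.3) and mu2 == pytest.approx(0.9 * 1.3)


class TestFit:
    def test_fully_observed_fidelity_dominates(self):
        A = np.ones((6, 5))
        hp = HyperParams(alpha=0.0, lam=0.0, beta=1e4)
        X, state = fit(A, np.eye(6), np.eye(5), hp)
        assert np.allclose(X, 1.0, atol=1e-2)

    def test_deterministic(self, default_synthetic):
        ds = default_synthetic.ds
        A = np.asarray(ds.M, dtype=float)
        X1, _ = fit(A, ds.DS, ds.TS, HyperParams())
        X2, _ = fit(A, ds.DS, ds.TS, HyperParams())
        assert np.array_equal(X1, X2)

    def test_convergence_on_default_synthetic(self, default_synthetic):
        ds = default_synthetic.ds
        hp = HyperParams()
        X, state = fit(np.asarray(ds.M, dtype=float), ds.DS, ds.TS, hp)
        assert state.converged
        assert state.iter <= hp.max_iter
        r1, r2 = state.primal_residuals[-1]
        assert max(r1, r2) <= hp.tol

    def test_augmented_lagrangian_monotone_within_iteration(self, default_synthetic):
        # each of the three block updates minimizes the AL exactly in its
        # block, so the AL value cannot increase across them
        ds = default_synthetic.ds
        A = np.asarray(ds.M, dtype=float)
        hp = HyperParams(max_iter=60)
        laps = laplacian_pair(ds.DS, ds.TS)
        st = ALMState(
            X=A.copy(), J=A.copy(), Z=A.copy(),
            Y1=np.zeros_like(A), Y2=np.zeros_like(A),
            mu1=hp.mu1_init, mu2=hp.mu2_init,
        )
        for _ in range(60):
            before = augmented_lagrangian(st, A, laps, hp)
            st.J = update_J(st.X, st.Y1, st.mu1)
            after_j = augmented_lagrangian(st, A, laps, hp)
            st.Z = update_Z(st.X, st.Y2, st.mu2, A, hp.beta)
            after_z = augmented_lagrangian(st, A, laps, hp)
            st.X = update_X(st.J, st.Z, st.Y1, st.Y2, st.mu1, st.mu2, laps, hp)
            after_x = augmented_lagrangian(st, A, laps, hp)
            slack = 1e-8 * (1 + abs(before))
            assert after_j <= before + slack
            assert after_z <= after_j + slack
            assert after_x <= after_z + slack
            st.Y1, st.Y2, st.mu1, st.mu2 = update_multipliers(st, hp)

    def test_nonbinary_training_matrix_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(np.full((3, 3), 0.5), np.eye(3), np.eye(3), HyperParams())

    def test_max_iter_warning_and_flag(self, default_synthetic):
        ds = default_synthetic.ds
        hp = HyperParams(max_iter=3)
        with pytest.warns(UserWarning, match="did not converge"):
            _, state = fit(np.asarray(ds.M, dtype=float), ds.DS, ds.TS, hp)
        assert not state.converged


class TestPlainMatrixCompletion:
    def test_fully_observed_recovers_matrix(self, rng):
        M = rng.uniform(0.5, 1.5, (5, 5))
        X = plain_matrix_completion(M)
        assert np.linalg.norm(X - M) / np.linalg.norm(M) <= 1e-3

    def test_rank_one_recovery_from_partial_observations(self):
        rng = np.random.default_rng(0)
        u, v = rng.uniform(0.5, 1.5, 5), rng.uniform(0.5, 1.5, 5)
        M = np.outer(u, v)
        obs = set()
        while len(obs) < 20:  # 80% observed
            obs.add((int(rng.integers(5)), int(rng.integers(5))))
        X = plain_matrix_completion(M, obs)
        assert np.linalg.norm(X - M) / np.linalg.norm(M) <= 1e-2

    def test_observed_entries_reproduced(self, rng):
        M = rng.uniform(0, 1, (6, 4))
        obs = {(i, j) for i in range(6) for j in range(4) if rng.uniform() < 0.7}
        obs.add((0, 0))
        X = plain_matrix_completion(M, obs)
        idx = tuple(zip(*obs))
        rel = np.linalg.norm(X[idx[0], idx[1]] - M[idx[0], idx[1]]) / np.linalg.norm(
            M[idx[0], idx[1]]
        )
        assert rel <= 1e-3

    def test_empty_observed_set_rejected(self):
        with pytest.raises(ValueError):
            plain_matrix_completion(np.ones((3, 3)), set())
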