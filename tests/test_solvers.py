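"""Solver behavior: recovery, monotonicity, constraints, cross-checks."""

import numpy as np
import pytest
import scipy.optimize

import snm3f as sf
from snm3f.solvers import _kkt_solve, _qp_module_step
from conftest import random_instance


class TestSnm3f:
    def test_noise_free_recovery(self, toy_clean):
        r = sf.fit_snm3f(
            toy_clean.dataset, 2, 2, sf.FitOptions(n_restarts=5, seed=0)
        )
        assert sf.vaf(toy_clean.dataset, r.model) >= 0.999

    def test_degenerate_identical_trials(self):
        # S copies of one rank-1 pattern: the fit succeeds with ~zero error,
        # VAF itself is undefined (zero scatter about the mean)
        pattern = np.outer([0.4, 0.6], [0.3, 0.7])
        data = sf.EMGDataset(np.repeat(pattern[None], 5, axis=0))
        r = sf.fit_snm3f(data, 1, 1, sf.FitOptions(n_restarts=3, seed=0))
        assert r.final_e_nmf == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(Exception):
            sf.vaf(data, r.model)

    def test_error_history_is_non_increasing(self, rng):
        for _ in range(5):
            X, _, _, _, _ = random_instance(rng, S=8, T=4, M=3, P=2, N=2)
            r = sf.fit_snm3f(
                sf.EMGDataset(X), 2, 2, sf.FitOptions(max_iter=150, seed=3)
            )
            h = r.history.e_nmf
            assert np.all(np.diff(h) <= 1e-9 * h[0])

    def test_rejects_too_many_modules(self, toy_noisy):
        with pytest.raises(ValueError):
            sf.fit_snm3f(toy_noisy.dataset, 3, 2)  # P > T

    def test_unit_sum_and_nonnegativity(self, toy_noisy):
        r = sf.fit_snm3f(toy_noisy.dataset, 2, 2, sf.FitOptions(seed=0))
        m = r.model
        assert np.allclose(m.temporal_modules.sum(axis=0), 1.0, atol=1e-8)
        assert np.allclose(m.spatial_modules.sum(axis=1), 1.0, atol=1e-8)
        assert m.temporal_modules.min() >= 0 and m.coefficients.min() >= 0


class TestDsnm3fMult:
    def test_zero_weights_reduce_to_snm3f(self, toy_noisy):
        opts = sf.FitOptions(n_restarts=2, seed=7, max_iter=120)
        r0 = sf.fit_snm3f(toy_noisy.dataset, 2, 2, opts)
        r1 = sf.fit_dsnm3f_mult(
            toy_noisy.dataset, toy_noisy.dataset.labels, 2, 2,
            sf.DiscriminationParams(0.0, 0.0), opts,
        )
        assert np.max(np.abs(r0.history.e_nmf - r1.history.e_nmf)) < 1e-12
        assert np.array_equal(r0.model.coefficients, r1.model.coefficients)

    def test_noise_free_four_task_decoding_is_perfect(self, toy_clean):
        d = toy_clean.dataset
        r = sf.fit_dsnm3f_mult(
            d, d.labels, 2, 2, sf.toy_tuned_params(),
            sf.FitOptions(n_restarts=5, seed=0),
        )
        assert sf.lda_decode_loo(r.model.coefficients, d.labels) == 1.0

    def test_update_split_reassembles_gradient(self, rng):
        # the numerator/denominator split of the multiplicative rule must
        # equal the analytic gradient of E^2 wrt the coefficients
        for _ in range(5):
            X, labels, Wt, A, Ws = random_instance(rng, S=9, K=3)
            data = sf.EMGDataset(X, labels)
            model = sf.SpaceByTimeModel(Wt, Ws, A)
            params = sf.DiscriminationParams(0.4, 0.2)
            grad = sf.grad_e2_coefficients(data, model, labels, params)
            h = 1e-6
            fd = np.zeros_like(A)

            def cost(a):
                return sf.total_cost(
                    data, sf.SpaceByTimeModel(Wt, Ws, a), labels, params
                )

            for idx in np.ndindex(A.shape):
                up, down = A.copy(), A.copy()
                up[idx] += h
                down[idx] -= h
                fd[idx] = (cost(up) - cost(down)) / (2 * h)
            assert np.max(np.abs(grad - fd)) / max(np.max(np.abs(fd)), 1e-12) < 1e-6

    def test_missing_labels_raise(self, toy_noisy):
        with pytest.raises(ValueError):
            sf.fit_dsnm3f_mult(
                toy_noisy.dataset, None, 2, 2, sf.DiscriminationParams(0.1, 0.0)
            )


class TestAls:
    def test_constraints_satisfied(self, toy_noisy):
        d = toy_noisy.dataset
        r = sf.fit_dsnm3f_als(
            d, d.labels, 2, 2, sf.toy_tuned_params(),
            sf.FitOptions(solver="als", n_restarts=2, seed=0, max_iter=60),
        )
        m = r.model
        assert np.allclose(m.temporal_modules.sum(axis=0), 1.0, atol=1e-8)
        assert np.allclose(m.spatial_modules.sum(axis=1), 1.0, atol=1e-8)
        assert m.temporal_modules.min() >= 0 and m.spatial_modules.min() >= 0

    def test_kkt_solution_matches_constrained_lsq_oracle(self, rng):
        # unclipped equality-constrained solution vs a generic SLSQP oracle
        T, P = 4, 2
        R = rng.uniform(0.2, 1.0, (5, P, 3))
        Xs = rng.uniform(0.2, 1.0, (5, T, 3))
        G = np.einsum("spm,sqm->pq", R, R)
        C = np.einsum("stm,spm->tp", Xs, R)
        sol = _kkt_solve(G, C, T, 1e-10)

        def fun(v):
            W = v.reshape((T, P), order="F")
            return float(np.sum((W @ G) * W) - 2.0 * np.sum(W * C))

        cons = [
            {"type": "eq", "fun": lambda v, j=j: v.reshape((T, P), order="F")[:, j].sum() - 1.0}
            for j in range(P)
        ]
        res = scipy.optimize.minimize(
            fun, np.full(T * P, 1.0 / T), constraints=cons, method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        oracle = res.x.reshape((T, P), order="F")
        assert np.max(np.abs(sol - oracle)) < 1e-6
        assert np.allclose(sol.sum(axis=0), 1.0, atol=1e-9)

    def test_qp_steps_never_increase_module_objective(self, rng):
        for _ in range(5):
            T, P = 4, 2
            R = rng.uniform(0.1, 1.0, (6, P, 3))
            Xs = rng.uniform(0.1, 1.0, (6, T, 3))
            G = np.einsum("spm,sqm->pq", R, R)
            C = np.einsum("stm,spm->tp", Xs, R)
            W0 = rng.uniform(0.1, 1.0, (T, P))
            W0 /= W0.sum(axis=0)

            def f(W):
                return float(np.sum((W @ G) * W) - 2.0 * np.sum(W * C))

            W1 = _qp_module_step(W0, G, C, T)
            assert f(W1) <= f(W0) + 1e-10
            assert W1.min() >= 0 and np.allclose(W1.sum(axis=0), 1.0, atol=1e-8)


class TestNlp:
    def test_constraints_and_noise_free_recovery(self, toy_clean):
        d = toy_clean.dataset
        r = sf.fit_dsnm3f_nlp(
            d, d.labels, 2, 2, sf.DiscriminationParams(),
            sf.FitOptions(n_restarts=3, seed=0, max_iter=300),
        )
        m = r.model
        assert np.max(np.abs(m.temporal_modules.sum(axis=0) - 1.0)) < 1e-6
        assert np.max(np.abs(m.spatial_modules.sum(axis=1) - 1.0)) < 1e-6
        assert m.temporal_modules.min() >= 0.0
        assert sf.vaf(d, r.model) >= 0.999

    def test_packed_gradient_matches_finite_differences(self, rng):
        from snm3f.solvers import _pack, _unpack

        X, labels, Wt, A, Ws = random_instance(rng)
        params = sf.DiscriminationParams(0.3, 0.1)
        S, T, M = X.shape
        P, N = Wt.shape[1], Ws.shape[0]
        z0 = _pack(Wt, A, Ws)

        def fun(z):
            wt, a, ws = _unpack(z, T, M, P, N, S)
            return sf.e2_with_gradients(X, wt, a, ws, labels, params)[0]

        v, gWt, gA, gWs = sf.e2_with_gradients(X, Wt, A, Ws, labels, params)
        g = _pack(gWt, gA, gWs)
        h = 1e-6
        fd = np.array([
            (fun(z0 + h * e) - fun(z0 - h * e)) / (2 * h)
            for e in np.eye(len(z0))
        ])
        assert np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1e-12) < 1e-5


class TestProjection:
    def test_recovers_exact_construction(self, rng):
        Wt = rng.uniform(0.2, 1.0, (4, 2))
        Wt /= Wt.sum(axis=0)
        Ws = rng.uniform(0.2, 1.0, (2, 3))
        Ws /= Ws.sum(axis=1, keepdims=True)
        A = rng.uniform(0.5, 2.0, (6, 2, 2))
        data = sf.EMGDataset(np.einsum("tp,spn,nm->stm", Wt, A, Ws))
        Ahat = sf.project_onto_modules(data, Wt, Ws)
        assert np.max(np.abs(Ahat - A) / A) < 1e-3

    def test_zero_trial_gives_zero_coefficients(self):
        Wt = np.array([[0.6, 0.3], [0.4, 0.7]])
        Ws = np.array([[0.5, 0.5], [0.2, 0.8]])
        data = sf.EMGDataset(np.zeros((1, 2, 2)))
        Ahat = sf.project_onto_modules(data, Wt, Ws)
        assert np.allclose(Ahat, 0.0, atol=1e-12)

    def test_fixed_point_of_converged_fit(self, toy_noisy):
        d = toy_noisy.dataset
        r = sf.fit_snm3f(
            d, 2, 2, sf.FitOptions(n_restarts=3, seed=0, max_iter=10_000, tol=1e-15)
        )
        Ahat = sf.project_onto_modules(
            d, r.model.temporal_modules, r.model.spatial_modules
        )
        scale = np.max(r.model.coefficients)
        assert np.max(np.abs(Ahat - r.model.coefficients)) / scale < 1e-3

    def test_dimension_mismatch(self, toy_noisy):
        with pytest.raises(ValueError):
            sf.project_onto_modules(
                toy_noisy.dataset, np.ones((3, 2)) / 3, np.ones((2, 2)) / 2
            )


class TestRestartsAndDeterminism:
    def test_identical_options_give_identical_history(self, toy_noisy):
        d = toy_noisy.dataset
        opts = sf.FitOptions(n_restarts=3, seed=11, max_iter=80)
        p = sf.toy_tuned_params()
        r1 = sf.fit_dsnm3f_mult(d, d.labels, 2, 2, p, opts)
        r2 = sf.fit_dsnm3f_mult(d, d.labels, 2, 2, p, opts)
        assert np.array_equal(r1.history.e2, r2.history.e2)
        assert np.array_equal(r1.model.coefficients, r2.model.coefficients)

    def test_best_cost_non_increasing_in_restart_budget(self, toy_noisy):
        d = toy_noisy.dataset
        costs = []
        for n in (1, 3, 6):
            r = sf.fit_snm3f(
                d, 2, 2, sf.FitOptions(n_restarts=n, seed=5, max_iter=120)
            )
            costs.append(r.final_e_nmf)
        assert costs[1] <= costs[0] + 1e-12 and costs[2] <= costs[1] + 1e-12

    def test_final_cost_matches_recomputation(self, toy_noisy):
        d = toy_noisy.dataset
        p = sf.toy_tuned_params()
        r = sf.fit_dsnm3f_mult(
            d, d.labels, 2, 2, p, sf.FitOptions(n_restarts=2, seed=0, max_iter=100)
        )
        recomputed = sf.total_cost(d, r.model, d.labels, p)
        assert r.final_cost == pytest.approx(recomputed, rel=1e-8)
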