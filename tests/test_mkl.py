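"""Reduced-gradient MKL: gradients, directions, descent, optimality."""

import numpy as np
import pytest

from conftest import grams_for, random_toy_problem, slsqp_dual_objective
from hmkl.kernels import KernelSpec, gram, linear_kernel, rbf_kernel
from hmkl.mkl import (MKLModel, MKLProblem, check_kkt, duality_gap, fit,
                      gradient_f, line_search, objective_f, predict,
                      reduced_gradient_direction)
from hmkl.svm_dual import decision_values, solve_svm_dual


def three_kernel_problem(seed, n=8, C=1.0):
    X, y = random_toy_problem(seed, n=n)
    specs = [KernelSpec("hadamard", 1.0), KernelSpec("rbf", 1.0),
             KernelSpec("linear")]
    return X, MKLProblem(specs, grams_for(specs, X), y, C=C)


class TestObjective:
    def test_single_kernel_collapse(self, toy_problem):
        X, y = toy_problem
        K = linear_kernel(X)
        prob = MKLProblem([KernelSpec("linear")], [K], y, C=1.0)
        f, a, b = objective_f(np.array([1.0]), prob)
        sol = solve_svm_dual(K, y, C=1.0)
        assert f == pytest.approx(sol.objective, abs=1e-8)

    def test_simplex_vertex_equals_first_kernel(self, toy_problem):
        X, y = toy_problem
        specs = [KernelSpec("linear"), KernelSpec("rbf", 1.0),
                 KernelSpec("hadamard", 1.0)]
        prob = MKLProblem(specs, grams_for(specs, X), y, C=1.0)
        f_vertex, _, _ = objective_f(np.array([1.0, 0.0, 0.0]), prob)
        f_single = solve_svm_dual(linear_kernel(X), y, C=1.0).objective
        assert f_vertex == pytest.approx(f_single, abs=1e-8)

    def test_matches_brute_force_on_mixture(self):
        X, prob = three_kernel_problem(21, n=10)
        d = np.full(3, 1 / 3)
        f, _, _ = objective_f(d, prob, tol=1e-9)
        oracle = slsqp_dual_objective(prob.combined(d), prob.y, C=1.0)
        assert f == pytest.approx(oracle, abs=1e-6)


class TestGradient:
    def test_zero_alpha(self):
        grads = gradient_f(np.zeros(4), np.ones(4), [np.eye(4), 2 * np.eye(4)])
        assert np.all(grads == 0.0)

    def test_duplicated_kernels_equal_components(self, toy_problem):
        X, y = toy_problem
        K = linear_kernel(X).values
        a = np.random.default_rng(0).uniform(0, 1, len(y))
        g = gradient_f(a, y, [K, K.copy()])
        assert g[0] == pytest.approx(g[1], abs=1e-14)

    def test_nonpositive_on_psd_kernels(self):
        X, prob = three_kernel_problem(5)
        _, a, _ = objective_f(np.full(3, 1 / 3), prob)
        g = gradient_f(a, prob.y, prob.grams)
        assert np.all(g <= 1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_finite_difference_agreement(self, seed):
        # analytic gradient differences vs central differences of f(d)
        # within the simplex-affine plane
        X, prob = three_kernel_problem(seed)
        d = np.array([0.3, 0.3, 0.4])
        _, a, _ = objective_f(d, prob, tol=1e-10)
        g = gradient_f(a, prob.y, prob.grams)
        h = 1e-5
        for m in range(2):
            e = np.zeros(3)
            e[m], e[2] = h, -h
            fp, _, _ = objective_f(d + e, prob, tol=1e-10)
            fm, _, _ = objective_f(d - e, prob, tol=1e-10)
            fd = (fp - fm) / (2 * h)
            analytic = g[m] - g[2]
            assert fd == pytest.approx(analytic, rel=1e-3, abs=1e-8)


class TestDirection:
    def test_uniform_gradient_is_stationary(self):
        D = reduced_gradient_direction(np.array([0.5, 0.3, 0.2]),
                                       np.array([-2.0, -2.0, -2.0]), mu=0)
        assert np.all(D == 0.0)

    def test_descent_and_simplex_plane(self):
        d = np.array([0.5, 0.5])
        grad = np.array([-1.0, -2.0])
        D = reduced_gradient_direction(d, grad, mu=0)
        assert abs(D.sum()) < 1e-14
        assert grad @ D < 0

    def test_frozen_boundary_coordinate(self):
        # a zero-weight coordinate whose re-entry would raise f stays put
        d = np.array([0.0, 1.0])
        grad = np.array([-1.0, -2.0])  # df/dd_0 - df/dd_1 = 1 > 0
        D = reduced_gradient_direction(d, grad, mu=1)
        assert D[0] == 0.0 and D[1] == 0.0

    def test_boundary_reentry_when_favourable(self):
        d = np.array([0.0, 1.0])
        grad = np.array([-3.0, -1.0])
        D = reduced_gradient_direction(d, grad, mu=1)
        assert D[0] > 0 and abs(D.sum()) < 1e-14

    def test_zero_pivot_rejected(self):
        with pytest.raises(ValueError, match="pivot"):
            reduced_gradient_direction(np.array([0.0, 1.0]),
                                       np.array([-1.0, -1.0]), mu=0)


class TestLineSearch:
    def test_feasible_step_range(self):
        X, y = random_toy_problem(2)
        specs = [KernelSpec("linear"), KernelSpec("rbf", 1.0)]
        prob = MKLProblem(specs, grams_for(specs, X), y, C=1.0)
        d = np.array([0.5, 0.5])
        D = np.array([-0.5, 0.5])
        gamma, d_next, f_next, a, b = line_search(d, D, prob)
        assert 0 <= gamma <= 1.0 + 1e-12  # component 0 hits zero at gamma=1
        assert np.all(d_next >= 0) and abs(d_next.sum() - 1) < 1e-12

    def test_not_worse_than_gamma_grid(self):
        X, y = random_toy_problem(6)
        specs = [KernelSpec("linear"), KernelSpec("hadamard", 1.0)]
        prob = MKLProblem(specs, grams_for(specs, X), y, C=1.0)
        d = np.array([0.6, 0.4])
        f0, a0, _ = objective_f(d, prob, tol=1e-9)
        g = gradient_f(a0, y, prob.grams)
        D = reduced_gradient_direction(d, g, mu=0)
        if np.max(np.abs(D)) < 1e-14:
            pytest.skip("already stationary")
        gamma, d_next, f_next, _, _ = line_search(d, D, prob, f_current=f0,
                                                  alpha0=a0, inner_tol=1e-9)
        neg = D < 0
        gmax = float(np.min(-d[neg] / D[neg]))
        grid_best = min(
            objective_f(np.clip(d + t * D, 0, None) /
                        np.clip(d + t * D, 0, None).sum(), prob,
                        tol=1e-9)[0]
            for t in np.linspace(0, gmax, 20))
        assert f_next <= grid_best + 1e-6


class TestDualityGap:
    def test_single_kernel_telescopes_to_zero(self, toy_problem):
        X, y = toy_problem
        K = linear_kernel(X)
        sol = solve_svm_dual(K, y, C=1.0, tol=1e-10)
        gap = duality_gap(sol.objective, sol.alpha, y, [K])
        assert abs(gap) < 1e-10 * max(1.0, sol.alpha.sum())

    def test_duplicated_kernels_zero_gap(self, toy_problem):
        X, y = toy_problem
        K = rbf_kernel(X, 1.0)
        prob = MKLProblem([KernelSpec("rbf", 1.0)] * 2,
                          [K, K], y, C=1.0)
        for d in (np.array([0.5, 0.5]), np.array([0.2, 0.8])):
            f, a, _ = objective_f(d, prob, tol=1e-10)
            gap = duality_gap(f, a, y, prob.grams)
            assert abs(gap) < 1e-8 * max(1.0, a.sum())

    def test_nonnegative_at_inner_optimum(self):
        X, prob = three_kernel_problem(17)
        f, a, _ = objective_f(np.full(3, 1 / 3), prob, tol=1e-10)
        assert duality_gap(f, a, prob.y, prob.grams) >= -1e-8


class TestFit:
    def test_single_kernel_equivalence(self, toy_problem):
        X, y = toy_problem
        spec = KernelSpec("linear")
        prob = MKLProblem([spec], [linear_kernel(X)], y, C=1.0)
        model = fit(prob, X_train=X)
        sol = solve_svm_dual(linear_kernel(X), y, C=1.0)
        ours, _ = predict(model, X)
        theirs = decision_values(sol.alpha, sol.b, y, linear_kernel(X).values)
        assert model.converged and abs(model.gap) < 1e-10 * max(1, sol.alpha.sum())
        assert np.max(np.abs(ours - theirs)) < 1e-6

    def test_duplicated_kernel_invariance(self, toy_problem):
        X, y = toy_problem
        K = linear_kernel(X)
        prob2 = MKLProblem([KernelSpec("linear")] * 2, [K, K], y, C=1.0)
        model2 = fit(prob2, X_train=X)
        sol = solve_svm_dual(K, y, C=1.0)
        scores2, _ = predict(model2, X)
        expect = decision_values(sol.alpha, sol.b, y, K.values)
        assert np.max(np.abs(scores2 - expect)) < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_simplex_and_monotone_descent(self, seed):
        X, prob = three_kernel_problem(seed, n=12)
        model = fit(prob, X_train=X)
        assert abs(model.d.sum() - 1.0) <= 1e-12
        assert np.min(model.d) >= -1e-12
        fs = [rec["f"] for rec in model.trace]
        assert all(b <= a + 1e-9 * max(1, abs(a)) for a, b in zip(fs, fs[1:]))

    def test_converged_gap_within_tolerance(self):
        X, prob = three_kernel_problem(33, n=14)
        model = fit(prob, tol_gap=1e-3, X_train=X)
        assert model.converged
        assert model.gap <= 1e-3 * max(model.alpha.sum(), 1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_simplex_grid_oracle(self, seed):
        # M = 2 problems: the learned mixture's f matches a dense grid
        # search with an independent QP solver at every grid point
        X, y = random_toy_problem(seed)
        specs = [KernelSpec("linear"), KernelSpec("rbf", 1.0)]
        grams = grams_for(specs, X)
        prob = MKLProblem(specs, grams, y, C=1.0)
        model = fit(prob, X_train=X)
        K1, K2 = (g.values for g in grams)
        grid = min(slsqp_dual_objective(t * K1 + (1 - t) * K2, y, C=1.0)
                   for t in np.linspace(0, 1, 101))
        assert model.f_value <= grid + 1e-3


class TestPredict:
    def test_training_scores_reproduced(self):
        X, prob = three_kernel_problem(44, n=10)
        model = fit(prob, X_train=X)
        scores, labels = predict(model, X)
        inner = decision_values(model.alpha, model.b, prob.y,
                                prob.combined(model.d))
        assert np.max(np.abs(scores - inner)) < 1e-10
        assert set(np.unique(labels)) <= {-1.0, 1.0}

    def test_vertex_matches_single_kernel(self, toy_problem):
        X, y = toy_problem
        spec = KernelSpec("hadamard", 1.0)
        K = gram(spec, X)
        sol = solve_svm_dual(K, y, C=1.0)
        model = MKLModel(d=np.array([1.0]), alpha=sol.alpha, b=sol.b,
                         kernel_list=[spec], X_train=X, y_train=y)
        scores, _ = predict(model, X)
        expect = decision_values(sol.alpha, sol.b, y, K.values)
        assert np.max(np.abs(scores - expect)) < 1e-10

    def test_matches_triple_loop_oracle(self):
        X, prob = three_kernel_problem(55, n=6)
        model = fit(prob, X_train=X)
        rng = np.random.default_rng(1)
        Xnew = np.abs(rng.normal(size=(3, X.shape[1]))) + 0.1
        scores, _ = predict(model, Xnew)
        from hmkl.kernels import cross_kernel
        for i in range(3):
            s = model.b
            for m, spec in enumerate(model.kernel_list):
                kc = cross_kernel(spec, X, Xnew[i:i + 1])[0]
                for j in range(len(prob.y)):
                    s += model.alpha[j] * prob.y[j] * model.d[m] * kc[j]
            assert scores[i] == pytest.approx(s, abs=1e-10)

    def test_dimension_mismatch(self):
        X, prob = three_kernel_problem(7)
        model = fit(prob, X_train=X)
        with pytest.raises(ValueError, match="feature count"):
            predict(model, np.ones((2, X.shape[1] + 1)))


class TestKKT:
    def test_converged_model_residuals(self):
        X, prob = three_kernel_problem(3, n=12)
        model = fit(prob, X_train=X, inner_tol=1e-8)
        rep = check_kkt(model, prob)
        assert rep["equality"] <= 1e-6
        assert rep["box"] <= 1e-9
        assert rep["simplex"] <= 1e-10

    def test_box_violation_flagged(self):
        X, prob = three_kernel_problem(3)
        model = fit(prob, X_train=X)
        model.alpha = model.alpha.copy()
        model.alpha[0] = 2.5  # outside [0, C]
        rep = check_kkt(model, problem=None, C=1.0)
        assert rep["box"] >= 1.5 - 1e-12

    def test_equality_violation_flagged(self):
        X, prob = three_kernel_problem(3)
        model = fit(prob, X_train=X)
        a = model.alpha.copy()
        a += 0.1 * (prob.y == 1) / np.sum(prob.y == 1)  # shift sum(a y) by 0.1
        model.alpha = a
        rep = check_kkt(model, problem=None, C=1.0)
        assert rep["equality"] == pytest.approx(0.1, abs=1e-9)
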