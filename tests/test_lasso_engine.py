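"""Solver correctness: closed forms, independent oracles, path structure."""

import numpy as np
import pytest

from helpers import (lasso_enumeration_oracle, lasso_objective,
                     orthonormal_design, soft_threshold, std_cols)

from lassogwas.lasso import (ConvergenceError, GramCache,
                             InvalidParameterError, cv_lambda,
                             default_lambda_grid, find_lambda_for_sparsity,
                             fit_lasso, kkt_violation, lambda_max,
                             partial_residual_ols)
from lassogwas.lasso import _sweep_naive


class TestFitLasso:
    def test_null_fit_at_lambda_max(self, small_regression):
        X, y, _ = small_regression
        lmax = lambda_max(X, y)
        assert fit_lasso(X, y, lmax).n_nonzero == 0
        assert fit_lasso(X, y, 0.99 * lmax).n_nonzero >= 1

    def test_unpenalized_limit_is_ols(self, small_regression):
        X, y, _ = small_regression
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        fit = fit_lasso(X, y, 0.0)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.3])
    def test_orthonormal_design_soft_threshold(self, lam):
        X = orthonormal_design(60, 5, seed=3)
        rng = np.random.default_rng(7)
        y = X @ np.array([0.5, -0.25, 0.12, 0.0, -0.6]) + rng.standard_normal(60)
        y -= y.mean()
        ols = X.T @ y / 60
        fit = fit_lasso(X, y, lam)
        np.testing.assert_allclose(fit.beta, soft_threshold(ols, lam), atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = std_cols(rng.standard_normal((30, 6)))
        y = X[:, 0] * 0.4 + rng.standard_normal(30)
        y -= y.mean()
        lam = 0.6 * lambda_max(X, y) * rng.uniform(0.3, 1.0)
        fit = fit_lasso(X, y, lam)
        beta_star = lasso_enumeration_oracle(X, y, lam)
        gap = lasso_objective(X, y, fit.beta, lam) - lasso_objective(
            X, y, beta_star, lam)
        assert abs(gap) < 1e-8

    def test_matches_sklearn(self, small_regression):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y, _ = small_regression
        lam = 0.05
        sk = sklearn_linear.Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                                  max_iter=10 ** 6).fit(X, y)
        np.testing.assert_allclose(fit_lasso(X, y, lam).beta, sk.coef_,
                                   atol=1e-7)

    def test_gram_and_naive_paths_agree(self, small_regression):
        X, y, _ = small_regression
        gram = GramCache(X)
        for lam in (0.01, 0.08, 0.2):
            np.testing.assert_allclose(
                fit_lasso(X, y, lam).beta,
                fit_lasso(X, y, lam, precompute=gram).beta, atol=1e-9)

    def test_kkt_invariant_and_nnz(self, small_regression):
        X, y, _ = small_regression
        fit = fit_lasso(X, y, 0.07)
        assert kkt_violation(X, y, fit.beta, fit.lam) < 1e-6
        assert fit.n_nonzero == np.count_nonzero(fit.beta)

    def test_negative_lambda_rejected(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(InvalidParameterError):
            fit_lasso(X, y, -0.1)

    def test_convergence_error_carries_violation(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(ConvergenceError) as err:
            fit_lasso(X, y, 1e-4, max_sweeps=1)
        assert err.value.kkt_violation > 0

    def test_objective_nonincreasing_across_sweeps(self, small_regression):
        X, y, _ = small_regression
        lam = 0.05
        beta = np.zeros(X.shape[1])
        r = y.copy()
        colnorm = np.einsum("ij,ij->j", X, X) / X.shape[0]
        objs = [lasso_objective(X, y, beta, lam)]
        for _ in range(25):
            _sweep_naive(X, r, beta, colnorm, lam, False)
            objs.append(lasso_objective(X, y, beta, lam))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))


class TestLambdaMax:
    def test_orthogonal_response_gives_zero(self):
        X = orthonormal_design(40, 3, seed=1)
        y = np.zeros(40)
        assert lambda_max(X, y) == 0.0

    def test_single_column_definition(self):
        rng = np.random.default_rng(0)
        x = std_cols(rng.standard_normal((50, 1)))
        y = 0.3 * x[:, 0]  # x'y/n = 0.3 exactly since x'x/n = 1
        assert lambda_max(x, y) == pytest.approx(0.3)

    def test_matches_brute_force_scan(self, rng):
        X = std_cols(rng.standard_normal((50, 8)))
        y = rng.standard_normal(50)
        brute = max(abs(X[:, j] @ y) / 50 for j in range(8))
        assert lambda_max(X, y) == pytest.approx(brute)


class TestSparsityBisection:
    def test_s_zero_returns_lambda_max(self, small_regression):
        X, y, _ = small_regression
        assert find_lambda_for_sparsity(X, y, 0) == lambda_max(X, y)

    def test_orthonormal_order_statistics(self):
        X = orthonormal_design(80, 6, seed=5)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(80)
        y -= y.mean()
        a = np.sort(np.abs(X.T @ y / 80))[::-1]
        for s in (1, 2, 4):
            lam = find_lambda_for_sparsity(X, y, s)
            assert a[s] < lam <= a[s - 1] + 1e-9

    def test_exact_count_and_grid_scan_oracle(self, rng):
        X = std_cols(rng.standard_normal((100, 20)))
        y = X[:, :3] @ np.array([0.5, 0.4, -0.3]) + rng.standard_normal(100)
        y -= y.mean()
        lam = find_lambda_for_sparsity(X, y, 3)
        assert fit_lasso(X, y, lam).n_nonzero == 3
        lmax = lambda_max(X, y)
        grid = np.linspace(lam + 2e-6 * lmax, lmax, 10_000)  # above bisection tol
        gram = GramCache(X)
        counts = np.array([fit_lasso(X, y, g, precompute=gram).n_nonzero
                           for g in grid])
        assert not np.any(counts == 3)  # no larger qualifying penalty

    def test_nnz_monotone_along_trace(self, rng):
        X = std_cols(rng.standard_normal((150, 30)))
        y = rng.standard_normal(150)
        y -= y.mean()
        _, trace = find_lambda_for_sparsity(X, y, 5, return_trace=True)
        lams, counts = zip(*sorted(trace))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_s_beyond_p_rejected(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(InvalidParameterError):
            find_lambda_for_sparsity(X, y, X.shape[1] + 1)


class TestPartialResidualOls:
    def test_zero_beta_gives_marginal_covariance(self, small_regression):
        X, y, _ = small_regression
        n = X.shape[0]
        for j in (0, 3):
            assert partial_residual_ols(X, y, np.zeros(X.shape[1]), j) == \
                pytest.approx(X[:, j] @ y / n)

    def test_kkt_identities_at_solution(self, small_regression):
        X, y, _ = small_regression
        lam = 0.08
        fit = fit_lasso(X, y, lam)
        for j in range(X.shape[1]):
            pr = partial_residual_ols(X, y, fit.beta, j)
            if fit.beta[j] != 0:
                assert pr == pytest.approx(
                    fit.beta[j] + lam * np.sign(fit.beta[j]), abs=1e-5)
            else:
                assert abs(pr) <= lam + 1e-6

    def test_index_out_of_range(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(IndexError):
            partial_residual_ols(X, y, np.zeros(X.shape[1]), X.shape[1])


class TestCvLambda:
    def test_determinism(self, small_regression):
        X, y, _ = small_regression
        a = cv_lambda(X, y, seed=11)
        b = cv_lambda(X, y, seed=11)
        assert a.lambda_selected == b.lambda_selected
        np.testing.assert_array_equal(a.cv_error, b.cv_error)

    def test_selected_attains_minimum(self, small_regression):
        X, y, _ = small_regression
        res = cv_lambda(X, y, seed=2)
        assert res.cv_error[res.lambda_grid == res.lambda_selected][0] == \
            res.cv_error.min()

    def test_pure_noise_selects_heavy_penalty(self):
        # with a single useless predictor the null fit wins CV in expectation
        rng = np.random.default_rng(31)
        selected_ratio = []
        for _ in range(100):
            x = std_cols(rng.standard_normal((60, 1)))
            y = rng.standard_normal(60)
            y -= y.mean()
            res = cv_lambda(x, y, seed=int(rng.integers(2 ** 31)))
            selected_ratio.append(res.lambda_selected / lambda_max(x, y))
        assert np.median(selected_ratio) >= 0.5

    def test_cv_penalty_grows_with_null_snps(self):
        # with no nulls CV barely penalizes; adding nulls pushes the
        # selected penalty toward the causal effect size
        from lassogwas.simdata import ScenarioConfig, make_scenario

        means = {}
        for p0 in (0, 45):
            vals = []
            for s in range(10):
                G, ph = make_scenario(ScenarioConfig(p0=p0, seed=300 + s))
                y = ph.values - ph.values.mean()
                vals.append(cv_lambda(G.values, y, seed=s).lambda_selected)
            means[p0] = np.mean(vals)
        assert means[0] < 0.005          # near-unpenalized regime
        assert 0.02 < means[45] < 0.08   # heavy-penalty regime
        assert means[45] > 10 * means[0]

    def test_empty_grid_rejected(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(InvalidParameterError):
            cv_lambda(X, y, grid=np.array([]))

    def test_default_grid_shape(self, small_regression):
        X, y, _ = small_regression
        grid = default_lambda_grid(X, y)
        assert grid.size == 100
        assert grid[0] == pytest.approx(lambda_max(X, y))
        assert np.all(np.diff(grid) < 0)
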