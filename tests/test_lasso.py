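"""Solver correctness: soft threshold, KKT, oracles, paths, cross-validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.linear_model import Lasso as SkLasso

from snplasso.lasso import (
    check_kkt,
    cross_validate,
    default_lambda_grid,
    fit_lasso,
    fit_path,
    lambda_max,
    select_at,
    soft_threshold,
)
from snplasso.preprocess import standardize_arrays

from conftest import convex_oracle, random_design


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,g,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.0, 0.0, 0.0)]
    )
    def test_examples(self, z, g, expected):
        assert soft_threshold(z, g) == pytest.approx(expected)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0, 50, allow_nan=False),
    )
    def test_odd_symmetry_and_shrinkage(self, z, g):
        s = soft_threshold(z, g)
        assert soft_threshold(-z, g) == -s
        assert abs(s) <= abs(z)
        if abs(z) <= g:
            assert s == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestLambdaMax:
    def test_orthogonal_response_gives_zero(self):
        n = 8
        X = np.zeros((n, 1))
        X[:4, 0], X[4:, 0] = 1.0, -1.0  # unit 1/n-variance, mean 0
        y = np.concatenate([np.ones(4), np.ones(4)])  # orthogonal to x
        d = standardize_arrays(X + 0.0, np.empty((n, 0)), y * 0, ["a"], [])
        d.y = y - y.mean()
        assert lambda_max(d) == pytest.approx(0.0)

    def test_single_column_definition(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        x = (x - x.mean()) / x.std()
        y = 0.7 * x
        d = standardize_arrays(
            x[:, None], np.empty((50, 0)), np.zeros(50), ["a"], []
        )
        d.y = y
        assert lambda_max(d) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_support_empty_above_and_nonempty_below(self, seed):
        d = random_design(seed, n=50, p=10)
        lm = lambda_max(d)
        assert fit_lasso(d, lm * 1.000001).support == set()
        assert fit_lasso(d, lm * 0.99).support != set()


class TestFitLasso:
    @pytest.mark.parametrize("seed", range(5))
    def test_at_lambda_max_covariates_equal_ols(self, seed):
        d = random_design(seed)
        fit = fit_lasso(d, lambda_max(d) * 1.01)
        assert fit.support == set()
        gamma_ols = np.linalg.lstsq(d.Z, d.y, rcond=None)[0]
        np.testing.assert_allclose(fit.gamma, gamma_ols, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_lambda_zero_matches_ols(self, seed):
        d = random_design(seed, n=60, p=8)
        fit = fit_lasso(d, 0.0)
        W = np.concatenate([d.X, d.Z], axis=1)
        ols = np.linalg.lstsq(W, d.y, rcond=None)[0]
        np.testing.assert_allclose(
            np.concatenate([fit.beta, fit.gamma]), ols, atol=1e-6
        )

    def test_agrees_with_generic_convex_solver(self):
        # >= 20 random instances x several lambdas: objective within 1e-5
        for seed in range(20):
            d = random_design(seed, n=40, p=8, q=3)
            lm = lambda_max(d)
            for frac in (0.8, 0.3, 0.05):
                fit = fit_lasso(d, lm * frac)
                _, _, obj_oracle = convex_oracle(d, lm * frac)
                assert fit.objective_value <= obj_oracle + 1e-5
                assert abs(fit.objective_value - obj_oracle) <= 1e-5 * max(
                    1.0, obj_oracle
                )

    def test_agrees_with_sklearn_without_covariates(self):
        # same objective convention as sklearn's Lasso on centered data
        for seed in range(5):
            d = random_design(seed, n=60, p=12, q=0)
            lam = lambda_max(d) * 0.2
            fit = fit_lasso(d, lam)
            sk = SkLasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=100000)
            sk.fit(d.X, d.y)
            np.testing.assert_allclose(fit.beta, sk.coef_, atol=1e-6)

    def test_objective_never_increases_during_descent(self):
        d = random_design(1, n=80, p=15)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # the descent guard warns on increase
            fit_lasso(d, lambda_max(d) * 0.1)

    def test_snp_column_permutation_only_renames(self):
        d = random_design(7, n=50, p=10)
        lam = lambda_max(d) * 0.2
        fit = fit_lasso(d, lam)
        perm = np.random.default_rng(0).permutation(10)
        d2 = standardize_arrays(
            d.X_raw[:, perm], d.Z_raw, d.y_raw,
            [d.snp_ids[j] for j in perm], d.covariate_names,
        )
        fit2 = fit_lasso(d2, lam)
        assert fit.support == fit2.support
        for sid, c in fit.coef_penalized.items():
            assert fit2.coef_penalized[sid] == pytest.approx(c, abs=1e-8)


class TestKkt:
    @pytest.mark.parametrize("frac", [0.5, 0.1, 0.02])
    def test_converged_fits_satisfy_stationarity(self, frac):
        for seed in range(5):
            d = random_design(seed, n=50, p=12)
            fit = fit_lasso(d, lambda_max(d) * frac)
            assert fit.converged
            assert check_kkt(fit, d)["worst"] < 1e-6

    def test_perturbed_coefficient_violates(self):
        d = random_design(2, n=50, p=8)
        fit = fit_lasso(d, lambda_max(d) * 0.2)
        j = int(np.flatnonzero(fit.beta)[0])
        fit.beta[j] += 0.1
        assert check_kkt(fit, d)["worst"] > 1e-3

    def test_empty_support_fit_strictly_feasible(self):
        d = random_design(3)
        fit = fit_lasso(d, lambda_max(d) * 1.5)
        rep = check_kkt(fit, d, tol=1e-8)
        assert rep["ok"]


class TestPath:
    def test_first_point_has_empty_support(self):
        for seed in range(3):
            path = fit_path(random_design(seed, n=40, p=12), n_lambda=30)
            assert path.fits[0].support == set()

    def test_support_grows_from_first_to_last(self):
        for seed in range(3):
            path = fit_path(random_design(seed, n=60, p=10), n_lambda=30)
            assert len(path.fits[-1].support) >= len(path.fits[0].support)

    def test_warm_start_is_pure_acceleration(self):
        d = random_design(5, n=50, p=10)
        path = fit_path(d, n_lambda=20)
        for lam, warm in zip(path.lambdas[::5], path.fits[::5]):
            cold = fit_lasso(d, lam)
            np.testing.assert_allclose(cold.beta, warm.beta, atol=1e-6)

    def test_dfmax_truncates_path(self):
        d = random_design(6, n=40, p=20)
        path = fit_path(d, n_lambda=50, dfmax=3)
        assert len(path.fits) < 50
        assert len(path.fits[-2].support) <= 3


class TestCrossValidate:
    def test_one_se_rule_never_below_lambda_min(self):
        for seed in range(3):
            d = random_design(seed, n=60, p=15)
            cv = cross_validate(d, K=5, n_repeats=3, seed=seed)
            for lo, hi in zip(cv.per_repeat_min, cv.per_repeat_1se):
                assert hi >= lo
            assert cv.lambda_1se >= cv.lambda_min

    def test_pure_noise_one_se_rule_selects_nothing(self):
        # null model: y independent of X; the 1-SE rule should pick an
        # empty SNP model in nearly every randomization
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 50))
            Z = rng.standard_normal((200, 3))
            y = rng.standard_normal(200)
            d = standardize_arrays(
                X, Z, y, [f"s{j}" for j in range(50)], ["a", "b", "c"]
            )
            cv = cross_validate(d, K=10, seed=seed)
            if len(select_at(d, cv.lambda_1se)) == 0:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_strong_signal_always_recovered(self):
        for seed in range(5):
            rng = np.random.default_rng(seed + 100)
            X = rng.standard_normal((120, 20))
            y = 2.0 * X[:, 4] + 0.1 * rng.standard_normal(120)
            d = standardize_arrays(
                X, np.empty((120, 0)), y, [f"s{j}" for j in range(20)], []
            )
            cv = cross_validate(d, K=10, seed=seed)
            assert "s4" in select_at(d, cv.lambda_min)
            assert "s4" in select_at(d, cv.lambda_1se)

    def test_selection_consistent_with_path_fit(self):
        d = random_design(9, n=50, p=10)
        path = fit_path(d, n_lambda=15)
        mid = len(path.fits) // 2
        assert select_at(d, float(path.lambdas[mid])) == path.fits[mid].support

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            cross_validate(random_design(0, n=15, p=4), K=10)


def test_grid_spans_requested_ratio():
    d = random_design(0, n=60, p=10)
    grid = default_lambda_grid(d, n_lambda=50, lambda_min_ratio=0.01)
    assert grid[0] == pytest.approx(lambda_max(d))
    assert grid[-1] == pytest.approx(grid[0] * 0.01)
    assert np.all(np.diff(grid) < 0)
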