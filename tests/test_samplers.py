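"""Sampling primitives and the univariate BRR/BayesB Gibbs engine."""

import numpy as np
import pytest
from scipy import stats

from mtgp.errors import DataValidationError
from mtgp.samplers import (ChainSettings, PredictorComponent, UnivariatePriors,
                           fit_univariate, sample_inverse_wishart,
                           sample_matrix_normal, sample_scaled_inv_chi2)


class TestChainSettings:
    def test_block_size_bounds(self):
        with pytest.raises(DataValidationError, match="block_size"):
            ChainSettings(n_iter=100, burn_in=10, block_size=10)
        with pytest.raises(DataValidationError, match="block_size"):
            ChainSettings(n_iter=100, burn_in=10, block_size=1000)

    def test_retained_sample_floor(self):
        with pytest.raises(DataValidationError, match="retained"):
            ChainSettings(n_iter=30, burn_in=20, thin=2)
        assert ChainSettings(n_iter=40, burn_in=20, thin=2).n_retained == 10

    def test_burnin_bounds(self):
        with pytest.raises(DataValidationError):
            ChainSettings(n_iter=100, burn_in=100)


class TestMatrixNormal:
    def test_zero_covariance_returns_location(self):
        rng = np.random.default_rng(0)
        M = np.arange(6.0).reshape(2, 3)
        draw = sample_matrix_normal(M, np.zeros((2, 2)), np.zeros((3, 3)), rng)
        np.testing.assert_array_equal(draw, M)

    def test_vec_covariance_identity(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_matrix_normal(np.zeros((2, 3)), np.eye(2),
                                               np.eye(3), rng).ravel()
                          for _ in range(20000)])
        cov = np.cov(draws.T)
        np.testing.assert_allclose(cov, np.eye(6), atol=0.05)

    def test_column_correlation(self):
        rng = np.random.default_rng(2)
        V = np.array([[1.0, 0.9], [0.9, 1.0]])
        draws = np.array([sample_matrix_normal(np.zeros((2, 2)), np.eye(2), V, rng)
                          for _ in range(20000)])
        corr = np.corrcoef(draws[:, 0, 0], draws[:, 0, 1])[0, 1]
        assert corr == pytest.approx(0.9, abs=0.02)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(3)
        with pytest.raises(DataValidationError):
            sample_matrix_normal(np.zeros((2, 3)), np.eye(3), np.eye(3), rng)


class TestInverseWishart:
    def test_moment_identity(self):
        rng = np.random.default_rng(4)
        draws = np.array([sample_inverse_wishart(10.0, 7.0 * np.eye(2), rng)
                          for _ in range(50000)])
        # mean = scale / (df - dim - 1) = 7 I / 7 = I
        np.testing.assert_allclose(draws.mean(axis=0), np.eye(2), atol=0.05)

    def test_dim1_matches_scaled_inv_chi2(self):
        rng = np.random.default_rng(5)
        df, tau2 = 6.0, 2.0
        draws = np.array([sample_inverse_wishart(df, np.array([[df * tau2]]), rng)[0, 0]
                          for _ in range(5000)])
        # IW(df, s) in dim 1 is Scale-inv-chi2(df, s/df)
        ks = stats.kstest(draws, lambda x: stats.invgamma.cdf(x, df / 2,
                                                              scale=df * tau2 / 2))
        assert ks.pvalue > 0.01

    def test_draws_symmetric_pd(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            d = sample_inverse_wishart(5.0, np.eye(3), rng)
            assert np.allclose(d, d.T)
            assert np.linalg.eigvalsh(d)[0] > 0

    def test_df_and_scale_validation(self):
        rng = np.random.default_rng(7)
        with pytest.raises(DataValidationError):
            sample_inverse_wishart(1.0, np.eye(3), rng)
        with pytest.raises(DataValidationError):
            sample_inverse_wishart(10.0, -np.eye(2), rng)


def test_scaled_inv_chi2_moments():
    rng = np.random.default_rng(8)
    df, s = 10.0, 3.0
    draws = np.array([sample_scaled_inv_chi2(df, s, rng) for _ in range(50000)])
    assert draws.mean() == pytest.approx(df * s / (df - 2), rel=0.03)


class TestFitUnivariate:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(10)
        n, q = 150, 12
        X = rng.standard_normal((n, q))
        y = X @ rng.standard_normal(q)
        st = ChainSettings(n_iter=600, burn_in=200, thin=2, seed=1)
        fit = fit_univariate(y, [PredictorComponent(X, "BRR")], st)
        assert np.corrcoef(y, fit.yhat)[0, 1] > 0.99

    def test_intercept_only_conjugate(self):
        rng = np.random.default_rng(11)
        y = rng.normal(5.0, 1.0, size=200)
        X = np.zeros((200, 1))
        st = ChainSettings(n_iter=1500, burn_in=500, thin=1, seed=2)
        fit = fit_univariate(y, [PredictorComponent(X, "BRR")], st)
        assert fit.intercept == pytest.approx(5.0, abs=0.2)

    def test_bayesb_spike_limit_collapses_to_intercept(self):
        rng = np.random.default_rng(12)
        n, q = 80, 10
        X = rng.standard_normal((n, q))
        y = 3.0 + rng.standard_normal(n)
        pri = UnivariatePriors(pi0=1.0 - 1e-9, p0=1e9, slab_scale=1e-10)
        st = ChainSettings(n_iter=400, burn_in=100, thin=1, seed=3)
        fit = fit_univariate(y, [PredictorComponent(X, "BayesB")], st, priors=pri)
        assert np.abs(fit.effects[0]).max() < 1e-3
        assert fit.intercept == pytest.approx(y.mean(), abs=0.3)

    def test_brr_matches_ridge_with_fixed_variances(self):
        rng = np.random.default_rng(13)
        n, q = 60, 8
        X = rng.standard_normal((n, q))
        y = X @ rng.standard_normal(q) + rng.standard_normal(n)
        s2, sc = 1.0, 0.8
        ridge = np.linalg.solve(X.T @ X / s2 + np.eye(q) / sc, X.T @ y / s2)
        st = ChainSettings(n_iter=8000, burn_in=1000, thin=1, seed=4)
        fit = fit_univariate(y, [PredictorComponent(X, "BRR")], st,
                             include_intercept=False, fixed_sigma2=s2,
                             fixed_component_variances=[sc])
        # posterior sd of each effect is bounded by sqrt(sc); chain is long
        # enough that MC error is a few percent of that
        assert np.abs(fit.effects[0] - ridge).max() < 0.05

    def test_missing_predictions_and_masking(self):
        rng = np.random.default_rng(14)
        n, q = 100, 10
        X = rng.standard_normal((n, q))
        y = X @ rng.standard_normal(q) + 0.1 * rng.standard_normal(n)
        y_missing = y.copy()
        y_missing[:20] = np.nan
        st = ChainSettings(n_iter=800, burn_in=300, thin=1, seed=5)
        fit = fit_univariate(y_missing, [PredictorComponent(X, "BRR")], st)
        assert fit.predictions.shape == (20,)
        assert np.isfinite(fit.predictions).all()
        assert np.corrcoef(y[:20], fit.predictions)[0, 1] > 0.8

    def test_same_seed_bitwise_reproducible(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((40, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(40)
        st = ChainSettings(n_iter=200, burn_in=50, thin=1, seed=42)
        comps = [PredictorComponent(X, "BRR")]
        a = fit_univariate(y, comps, st)
        b = fit_univariate(y, comps, st)
        np.testing.assert_array_equal(a.yhat, b.yhat)
        assert a.sigma2 == b.sigma2

    def test_unimplemented_models_raise(self):
        X = np.ones((10, 1))
        y = np.arange(10.0)
        st = ChainSettings(n_iter=100, burn_in=10, thin=1, seed=0)
        for label in ("BayesA", "BayesC", "BL"):
            with pytest.raises(NotImplementedError, match=label):
                fit_univariate(y, [PredictorComponent(X, label)], st)

    def test_all_missing_rejected(self):
        st = ChainSettings(n_iter=100, burn_in=10, thin=1, seed=0)
        with pytest.raises(DataValidationError):
            fit_univariate(np.full(5, np.nan),
                           [PredictorComponent(np.ones((5, 1)), "BRR")], st)

    def test_yhat_is_linear_in_posterior_means(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 4))
        y = X @ rng.standard_normal(4) + rng.standard_normal(30)
        st = ChainSettings(n_iter=300, burn_in=100, thin=2, seed=7)
        fit = fit_univariate(y, [PredictorComponent(X, "BRR")], st)
        np.testing.assert_allclose(fit.yhat, fit.intercept + X @ fit.effects[0],
                                   atol=1e-12)
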