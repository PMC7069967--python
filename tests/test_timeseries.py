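import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats
from sklearn.base import clone

from paleosize import timeseries as ts


def _ols(x, y):
    """Closed-form simple-regression oracle."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(beta / se), dof)
    return beta, se, p, np.sqrt(sigma2)


class TestAlignAndClean:
    def test_identity_at_lag_zero(self):
        pair = ts.align_and_clean([1.0, 2, 3, 4], [5.0, 6, 7, 8], lag=0)
        assert pair.n == 4
        assert np.array_equal(pair.response, [1, 2, 3, 4])

    def test_lag_one_pairs_with_preceding_sample(self):
        pair = ts.align_and_clean([1.0, 2, 3], [10.0, 20, 30], lag=1, min_pairs=2)
        assert np.array_equal(pair.response, [2, 3])
        assert np.array_equal(pair.predictor, [10, 20])

    def test_missing_rows_deleted_before_lagging(self):
        y = [1.0, 2, 3, 4, 5, 6]
        x = [1.0, 2, np.nan, 4, 5, 6]
        pair = ts.align_and_clean(y, x, lag=1)
        assert pair.n == 4
        assert np.array_equal(pair.response, [2, 4, 5, 6])
        assert np.array_equal(pair.predictor, [1, 2, 4, 5])

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="usable pairs"):
            ts.align_and_clean([1.0, 2, 3, 4], [1.0, 2, 3, 4], lag=1)

    def test_pandas_series_align_on_shared_index(self):
        idx = list("abcde")
        y = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        x = pd.Series([2.0, 3, 4, 5], index=idx[1:])
        pair = ts.align_and_clean(y, x, lag=0)
        assert pair.n == 4 and list(pair.index) == idx[1:]


class TestTrendTests:
    def test_monotone_series_has_unit_spearman(self):
        d = ts.trend_tests(np.array([1.0, 3.0, 3.5, 7.0, 9.0]))
        assert d.spearman_rho == pytest.approx(1.0)

    def test_constant_series_flat_and_nonsignificant(self):
        d = ts.trend_tests(np.full(6, 2.5))
        assert d.ols_slope == 0.0 and d.ols_p == 1.0
        assert not d.significant()

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=8)
        d = ts.trend_tests(y)
        beta, _, p, _ = _ols(np.arange(8.0), y)
        assert d.ols_slope == pytest.approx(beta[1], rel=1e-10)
        assert d.ols_p == pytest.approx(p[1], rel=1e-8)


class TestAutocorrDiagnostics:
    def test_acf_zero_lag_is_one(self):
        d = ts.autocorr_diagnostics(np.random.default_rng(0).normal(size=50))
        assert d.acf[0] == pytest.approx(1.0)

    def test_alternating_residuals_have_dw_three(self):
        d = ts.autocorr_diagnostics(np.array([1.0, -1, 1, -1]))
        assert d.durbin_watson == pytest.approx(3.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ts.autocorr_diagnostics(np.ones(8))

    def test_dw_in_valid_range_and_serious_flag(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=200)
        d = ts.autocorr_diagnostics(e)
        assert 0 <= d.durbin_watson <= 4
        ar = np.zeros(200)
        for t in range(1, 200):
            ar[t] = 0.9 * ar[t - 1] + e[t]
        assert ts.autocorr_diagnostics(ar).serious()


class TestGeneralizedDifference:
    def test_linear_series_maps_to_zero(self):
        out = ts.generalized_difference(2.0 + 0.7 * np.arange(10))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_rho_zero_returns_trailing_residuals(self):
        # residuals with exactly zero lag-1 autocovariance by construction
        r = np.array([1.0, -1.0, -1.0, 1.0] * 3)
        y = r - np.polyval(np.polyfit(np.arange(12), r, 1), np.arange(12))
        rho = np.dot(y[1:], y[:-1]) / np.dot(y, y)
        out = ts.generalized_difference(y)
        assert np.allclose(out, y[1:] - rho * y[:-1])
        assert abs(rho) < 0.2

    def test_whitens_ar1_residuals(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=500)
        x = np.zeros(500)
        for t in range(1, 500):
            x[t] = 0.7 * x[t - 1] + e[t]
        out = ts.generalized_difference(x)
        acf1 = ts.autocorr_diagnostics(out).acf[1]
        assert abs(acf1) < 0.1


class TestNdiffs:
    def test_white_noise_needs_none(self):
        x = np.random.default_rng(0).normal(size=200)
        assert ts.ndiffs(x) == 0
        assert ts.ndiffs(x, test="kpss") == 0

    def test_random_walk_needs_one(self):
        x = np.cumsum(np.random.default_rng(0).normal(size=200))
        assert ts.ndiffs(x) == 1

    def test_cap_honoured_on_pathological_input(self):
        x = np.exp(np.linspace(0, 12, 60)) * np.sin(np.arange(60))
        assert ts.ndiffs(x, max_d=5) <= 5


class TestAutoArima:
    def test_white_noise_selects_no_structure(self):
        x = np.random.default_rng(0).normal(size=300)
        assert ts.auto_arima(x).order == (0, 0, 0)

    def test_ar1_detected_with_coefficient_recovered(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=300)
        x = np.zeros(300)
        for t in range(1, 300):
            x[t] = 0.8 * x[t - 1] + e[t]
        fit = ts.auto_arima(x)
        assert fit.order[0] >= 1
        # ML consistency of the coefficient under the true model class
        ar1_fit = ts.auto_arima(x, max_p=1, max_q=0, d=0)
        assert ar1_fit.order == (1, 0, 0)
        assert ar1_fit.ar[0] == pytest.approx(0.8, abs=0.15)

    def test_stepwise_agrees_with_grid_on_clear_structure(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=400)
        x = np.zeros(400)
        for t in range(1, 400):
            x[t] = 0.6 * x[t - 1] + e[t]
        assert ts.auto_arima(x).order == ts.auto_arima(x, stepwise=False).order


class TestArmaGLS:
    def test_perfect_fit(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = ts.gls_arma((np.array([0.0, 1, 2]), np.array([0.0, 1, 2])), (0, 0))
        assert fit.slope == pytest.approx(1.0)
        assert fit.residual_std_error == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_ols(self):
        x = np.array([0.0, 1, 2])
        y = np.array([1.0, 2, 4])
        fit = ts.gls_arma((y, x), (0, 0))
        assert fit.slope == pytest.approx(1.5, rel=1e-12)

    def test_order_00_equals_ols_everything(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = 1.0 + 0.5 * x + rng.normal(size=25)
        fit = ts.gls_arma((y, x), (0, 0))
        beta, se, p, sigma = _ols(x, y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(se[1], rel=1e-10)
        assert fit.slope_p == pytest.approx(p[1], rel=1e-10)
        assert fit.residual_std_error == pytest.approx(sigma, rel=1e-10)

    def test_profile_at_zero_ar_coefficient_reduces_to_ols(self):
        """Continuity: an AR(1) structure with phi = 0 is exactly OLS."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        est = ts.ArmaGLS(order=(1, 0))
        design = np.column_stack([np.ones(30), x])
        _, beta, _, _, ar, _ = est._profile(np.zeros(1), design, y)
        assert ar[0] == pytest.approx(0.0, abs=1e-12)
        oracle, _, _, _ = _ols(x, y)
        assert np.allclose(beta, oracle, rtol=1e-10)

    def test_arma_correlation_matrices_are_spd(self):
        est = ts.ArmaGLS()
        for phi in (-0.85, -0.3, 0.0, 0.4, 0.9):
            for theta in (-0.8, 0.0, 0.7):
                corr = est._arma_corr(np.array([phi]), np.array([theta]), 40)
                assert np.allclose(corr, corr.T)
                linalg.cholesky(corr)  # raises if not positive definite

    def test_constant_predictor_is_singular(self):
        with pytest.raises(Exception, match="singular"):
            ts.gls_arma((np.random.default_rng(0).normal(size=10), np.ones(10)), (0, 0))

    def test_agrees_with_statespace_regression_oracle(self):
        """Cross-check against statsmodels' regression-with-ARMA-errors
        (SARIMAX), an independent state-space implementation."""
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        rng = np.random.default_rng(11)
        n = 150
        x = rng.normal(size=n)
        e = np.zeros(n)
        eps = rng.normal(size=n)
        for t in range(1, n):
            e[t] = 0.6 * e[t - 1] + eps[t]
        y = 1.0 + 0.5 * x + e
        mine = ts.gls_arma((y, x), (1, 0), method="ML")
        ref = SARIMAX(y, exog=x, order=(1, 0, 0), trend="c").fit(disp=0)
        assert mine.slope == pytest.approx(ref.params[1], abs=0.02)
        assert mine.ar[0] == pytest.approx(ref.params[2], abs=0.05)

    def test_sklearn_estimator_protocol(self):
        est = ts.ArmaGLS(order=(1, 0), method="ML")
        est2 = clone(est)
        assert est2.get_params()["order"] == (1, 0)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 1))
        y = 0.5 * X[:, 0] + rng.normal(size=30)
        est2.fit(X, y)
        assert est2.predict(X).shape == (30,)
        assert hasattr(est2, "coef_") and hasattr(est2, "sigma_")


class TestCorrelationPipeline:
    def test_both_constant_fails_in_trend_stage(self):
        with pytest.raises(ts.PipelineStageError, match="trend_tests"):
            ts.run_correlation_pipeline(np.ones(10), np.ones(10))

    def test_deterministic_rerun_is_identical(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=25)
        x = rng.normal(size=25)
        a = ts.run_correlation_pipeline(y, x, lag=0)
        b = ts.run_correlation_pipeline(y, x, lag=0)
        assert a.order == b.order
        assert a.slope == b.slope and a.slope_p == b.slope_p
        assert a.differenced == b.differenced

    def test_delayed_response_detected_best_at_lag_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = np.empty(30)
        y[0] = rng.normal()
        y[1:] = x[:-1] + 0.3 * rng.normal(size=29)  # responds one level later
        t_abs = {}
        for lag in (0, 1):
            r = ts.run_correlation_pipeline(y, x, lag=lag)
            t_abs[lag] = abs(r.gls.slope / r.gls.slope_se)
        assert t_abs[1] > t_abs[0]

    def test_strong_dependence_recovered(self):
        rng = np.random.default_rng(9)
        x = np.r_[np.zeros(10), -np.ones(10), np.zeros(10)] + 0.1 * rng.normal(size=30)
        y = -2.0 * x + 0.3 * rng.normal(size=30)
        r = ts.run_correlation_pipeline(y, x, lag=0)
        assert r.slope < 0 and r.slope_p <= 0.05

    def test_report_row_shape(self):
        rng = np.random.default_rng(10)
        r = ts.run_correlation_pipeline(
            rng.normal(size=20), rng.normal(size=20), lag=1, label="toy"
        )
        row = r.as_row()
        assert set(row) == {
            "group", "lag", "p", "d", "q", "slope", "p_value",
            "correlation", "residual_std_error", "differenced", "n",
        }
        assert row["group"] == "toy" and row["lag"] == 1
        assert 0 <= row["p_value"] <= 1
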