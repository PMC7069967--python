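"""Correlation of palaeoecological time series with an isotope proxy.

Implements the full decision procedure used to regress a faunal series
(mean shell size or percentage of larger-sized individuals) on a d18O
series sampled at the same stratigraphic levels:

(i)    trend diagnostics of each series against sampling level (OLS and
       Spearman rank);
(ii)   autocorrelation diagnostics (ACF, Durbin-Watson) of the OLS
       residuals of the response~predictor relationship;
(iii') if a significant time trend coincides with serious autocorrelation,
       both series are detrended by generalized differencing
       (Cochrane-Orcutt-style removal of the fitted linear trend and the
       lag-1 residual autocorrelation);
(iii)  automatic ARIMA order selection (AICc over a small grid, degree of
       differencing from a KPSS/ADF stationarity battery) on the OLS
       residuals, with a stationarity re-check of the ARIMA residuals;
(iv)   generalized least squares with the selected ARMA(p,q) process as the
       residual correlation structure, fitted by profile maximum likelihood.

Series may be paired at lag 0 (same level) or lag 1 (each response value
against the predictor of the immediately preceding level) to probe a
delayed biological response.

The GLS-with-ARMA-errors model is exposed both as the sklearn-style
estimator :class:`ArmaGLS` and through the functional wrapper
:func:`gls_arma`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.stattools import durbin_watson as _durbin_watson
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.arima_process import arma_acovf
from statsmodels.tsa.statespace.tools import constrain_stationary_univariate
from statsmodels.tsa.stattools import acf as _acf
from statsmodels.tsa.stattools import adfuller, kpss

__all__ = [
    "AlignedPair",
    "TrendDiagnostics",
    "AutocorrDiagnostics",
    "ArimaFit",
    "GLSFit",
    "ArmaGLS",
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "align_and_clean",
    "trend_tests",
    "autocorr_diagnostics",
    "generalized_difference",
    "ndiffs",
    "auto_arima",
    "gls_arma",
    "run_correlation_pipeline",
]

logger = logging.getLogger("paleosize")


# ---------------------------------------------------------------------------
# alignment

@dataclass
class AlignedPair:
    """Response/predictor values paired after missing-row deletion and lagging."""

    response: np.ndarray
    predictor: np.ndarray
    index: np.ndarray
    lag: int
    n: int


def _as_values(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.Series):
        return series.to_numpy(float), np.asarray(series.index)
    arr = np.asarray(series, dtype=float)
    return arr, np.arange(len(arr))


def align_and_clean(response, predictor, lag: int = 0, min_pairs: int = 4) -> AlignedPair:
    """Pair two level-indexed series, deleting missing rows before lagging.

    Rows with a missing value in either series are removed first; the lag
    shift is then applied on the surviving ordered rows, so lag 1 pairs each
    response value with the predictor of the immediately preceding usable
    level.  Fewer than ``min_pairs`` resulting pairs is an error.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    y, idx_y = _as_values(response)
    x, idx_x = _as_values(predictor)
    if isinstance(response, pd.Series) and isinstance(predictor, pd.Series):
        common = response.index.intersection(predictor.index)
        y = response.loc[common].to_numpy(float)
        x = predictor.loc[common].to_numpy(float)
        idx = np.asarray(common)
    else:
        if len(y) != len(x):
            raise ValueError("series must share their level index")
        idx = idx_y
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x, idx = y[keep], x[keep], idx[keep]
    if lag:
        y, idx = y[lag:], idx[lag:]
        x = x[:-lag]
    n = len(y)
    if n < min_pairs:
        raise ValueError(f"only {n} usable pairs after cleaning/lagging (need >= {min_pairs})")
    return AlignedPair(response=y, predictor=x, index=idx, lag=lag, n=n)


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class TrendDiagnostics:
    """OLS and Spearman trend-in-time diagnostics of one series."""

    ols_slope: float
    ols_p: float
    spearman_rho: float
    spearman_p: float

    def significant(self, alpha: float = 0.05) -> bool:
        """Trend decision: the OLS p-value at the configured threshold
        (Spearman is reported for comparison only)."""
        return self.ols_p <= alpha


def trend_tests(series) -> TrendDiagnostics:
    """Regress a series on its sampling-level rank (0, 1, 2, ...).

    A constant series yields slope 0 with p = 1 rather than an error.
    """
    y, _ = _as_values(series)
    y = y[~np.isnan(y)]
    if len(y) < 4:
        raise ValueError("need at least 4 observations for trend diagnostics")
    t = np.arange(len(y), dtype=float)
    if np.ptp(y) == 0:
        return TrendDiagnostics(0.0, 1.0, 0.0, 1.0)
    ols = stats.linregress(t, y)
    rho, sp_p = stats.spearmanr(t, y)
    return TrendDiagnostics(float(ols.slope), float(ols.pvalue), float(rho), float(sp_p))


@dataclass
class AutocorrDiagnostics:
    """Sample ACF and Durbin-Watson statistic of a residual series."""

    acf: np.ndarray
    durbin_watson: float
    n: int
    band: float  # two-sided 95% white-noise band, 1.96/sqrt(n)
    significant_lags: list[int] = field(default_factory=list)

    def serious(self, dw_bounds: tuple[float, float] = (1.5, 2.5)) -> bool:
        """Serious autocorrelation: DW outside ``dw_bounds`` or any lag >= 1
        ACF value beyond the white-noise band."""
        lo, hi = dw_bounds
        return not (lo <= self.durbin_watson <= hi) or bool(self.significant_lags)


def autocorr_diagnostics(residuals, max_lag: int | None = None) -> AutocorrDiagnostics:
    """ACF (1/n normalisation) and Durbin-Watson of a residual series."""
    r, _ = _as_values(residuals)
    n = len(r)
    if n < 4:
        raise ValueError("need at least 4 residuals")
    if np.ptp(r) == 0:
        raise ValueError("zero-variance residuals; autocorrelation undefined")
    if max_lag is None:
        max_lag = min(10, n - 2)
    ac = _acf(r, nlags=max_lag, adjusted=False, fft=False)
    band = 1.96 / np.sqrt(n)
    sig = [k for k in range(1, len(ac)) if abs(ac[k]) > band]
    dw = float(_durbin_watson(r))
    return AutocorrDiagnostics(acf=ac, durbin_watson=dw, n=n, band=band, significant_lags=sig)


# ---------------------------------------------------------------------------
# detrending and stationarity

def generalized_difference(series) -> np.ndarray:
    """Remove a linear time trend and lag-1 residual autocorrelation.

    Residuals ``r`` of the series against its level rank are computed by
    OLS; with ``rho`` the lag-1 sample autocorrelation of ``r`` the
    transform returns ``r[t] - rho * r[t-1]`` for t >= 1 (length n-1).
    A perfectly linear series maps to zeros; ``rho = 0`` leaves the
    trailing residuals unchanged.
    """
    y, _ = _as_values(series)
    y = y[~np.isnan(y)]
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations to difference")
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    r = y - (intercept + slope * t)
    denom = float(np.dot(r, r))
    rho = float(np.dot(r[1:], r[:-1]) / denom) if denom > 0 else 0.0
    return r[1:] - rho * r[:-1]


def _is_stationary(x: np.ndarray, alpha: float, test: str) -> bool:
    if np.ptp(x) == 0:  # a constant is trivially stationary
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test in ("kpss", "both"):
            # KPSS must fail to reject level stationarity
            if kpss(x, regression="c", nlags="auto")[1] <= alpha:
                return False
        if test in ("adf", "both"):
            # ADF must reject a unit root
            if adfuller(x, regression="c", autolag="AIC")[1] > alpha:
                return False
    return True


def ndiffs(series, max_d: int = 5, alpha: float = 0.05, test: str = "both") -> int:
    """Degree of differencing needed for stationarity.

    Returns the smallest d <= ``max_d`` such that the d-times differenced
    series passes the chosen stationarity check at level ``alpha``, or
    ``max_d`` if it never passes.  ``test`` selects the battery: ``"kpss"``
    (non-rejection of stationarity; the convention automatic ARIMA order
    selection uses internally), ``"adf"`` (rejection of a unit root), or
    ``"both"`` (KPSS non-rejection and ADF rejection together; the default
    used for the post-fit stationarity confirmation).
    """
    if test not in ("kpss", "adf", "both"):
        raise ValueError(f"unknown stationarity test {test!r}")
    x, _ = _as_values(series)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError("need at least 8 observations for stationarity testing")
    for d in range(max_d + 1):
        xd = np.diff(x, n=d)
        if len(xd) < 8 or _is_stationary(xd, alpha, test):
            return d
    return max_d


# ---------------------------------------------------------------------------
# ARIMA order selection

@dataclass
class ArimaFit:
    """A fitted ARIMA(p,d,q) with its AICc and residual series."""

    order: tuple[int, int, int]
    ar: np.ndarray
    ma: np.ndarray
    sigma2: float
    aicc: float
    resid: np.ndarray


def _fit_arima(x: np.ndarray, p: int, d: int, q: int) -> ArimaFit | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(x, order=(p, d, q), trend="c" if d == 0 else "n").fit()
        aicc = float(res.aicc)
        if not np.isfinite(aicc):
            return None
    except Exception:  # non-convergence or numerical failure of one candidate
        return None
    return ArimaFit(
        order=(p, d, q),
        ar=np.asarray(res.arparams, float),
        ma=np.asarray(res.maparams, float),
        sigma2=float(res.params[-1]),
        aicc=aicc,
        resid=np.asarray(res.resid, float),
    )


def auto_arima(
    series,
    max_p: int = 2,
    max_q: int = 2,
    d: int | None = None,
    max_d: int = 5,
    alpha: float = 0.05,
    stepwise: bool = True,
) -> ArimaFit:
    """Select an ARIMA order by AICc.

    ``d`` defaults to :func:`ndiffs` on the series with the KPSS-only
    battery (the convention of automatic order selection; the stricter
    KPSS+ADF battery serves as the separate post-fit confirmation).
    Candidates are fitted by maximum likelihood.  By default the (p, q)
    space is explored with the conventional stepwise search of automatic
    ARIMA selection — initial set {(0,0), (1,0), (0,1), (2,2)} clipped to
    the bounds, then single-step neighbour moves from the current best —
    which compares fewer models than the exhaustive grid and is therefore
    less prone to spurious order choices on short series;
    ``stepwise=False`` scans the whole grid.  Candidates are visited in
    order of increasing p+q, then p, and must strictly improve the AICc to
    be adopted, so ties resolve toward the smaller model.  Raises if no
    candidate converges.
    """
    x, _ = _as_values(series)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError("need at least 8 observations for ARIMA selection")
    if d is None:
        d = ndiffs(x, max_d=max_d, alpha=alpha, test="kpss")

    def _key(pq):
        return (pq[0] + pq[1], pq[0], pq[1])

    fits: dict[tuple[int, int], ArimaFit | None] = {}

    def _fit(pq):
        if pq not in fits:
            fits[pq] = _fit_arima(x, pq[0], d, pq[1])
        return fits[pq]

    def _best_of(candidates, current):
        best = current
        for pq in sorted(candidates, key=_key):
            fit = _fit(pq)
            if fit is None:
                continue
            if best is None or fit.aicc < best.aicc - 1e-10:
                best = fit
        return best

    if stepwise:
        start = {
            (0, 0),
            (min(1, max_p), 0),
            (0, min(1, max_q)),
            (min(2, max_p), min(2, max_q)),
        }
        best = _best_of(start, None)
        while best is not None:
            p0, q0 = best.order[0], best.order[2]
            neighbours = {
                (p0 + dp, q0 + dq)
                for dp in (-1, 0, 1)
                for dq in (-1, 0, 1)
                if (dp, dq) != (0, 0)
                and 0 <= p0 + dp <= max_p
                and 0 <= q0 + dq <= max_q
            }
            improved = _best_of(neighbours - set(fits), best)
            if improved is best:
                break
            best = improved
    else:
        grid = [(p, q) for p in range(max_p + 1) for q in range(max_q + 1)]
        best = _best_of(grid, None)

    if best is None:
        raise RuntimeError("no ARIMA candidate converged")
    return best


# ---------------------------------------------------------------------------
# GLS with ARMA errors

@dataclass
class GLSFit:
    """Result of a GLS regression with ARMA-correlated errors."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    slope_p: float
    residual_std_error: float
    order: tuple[int, int]
    ar: np.ndarray
    ma: np.ndarray
    estimate_correlation: float
    n: int
    loglik: float


class ArmaGLS(RegressorMixin, BaseEstimator):
    """Linear regression with ARMA(p, q) error correlation, fitted by ML.

    The model is ``y_t = X_t beta + e_t`` where ``e`` follows a zero-mean
    stationary, invertible ARMA(p, q) process observed at equally spaced
    levels.  The error correlation matrix is the Toeplitz matrix of the
    ARMA autocorrelation; for fixed ARMA parameters ``beta`` and the
    innovation scale have closed-form GLS/ML solutions, so the ARMA
    parameters are estimated by profile maximum likelihood over a
    stationarity-constrained parameterisation.  With order (0, 0) the
    correlation matrix is the identity and the fit coincides with ordinary
    least squares.

    Parameters
    ----------
    order : tuple (p, q)
        AR and MA orders of the error process.
    fit_intercept : bool
        Include an intercept column (default True).
    method : {"REML", "ML"}
        Restricted (default, the convention of mixed/GLS model software)
        or plain maximum likelihood for the ARMA parameters and the
        innovation scale.  The regression coefficients are the GLS solution
        at the estimated correlation either way, so with order (0, 0) both
        methods coincide with OLS.

    Attributes
    ----------
    coef_, intercept_ : fitted regression coefficients.
    ar_, ma_ : fitted ARMA coefficients.
    sigma_ : residual standard error, from the whitened residual sum of
        squares on n - k degrees of freedom.
    params_cov_ : covariance matrix of [intercept, coef] estimates.
    pvalues_ : two-sided t-type p-values (n - k df) per coefficient.
    loglik_ : maximised log-likelihood.
    """

    def __init__(
        self,
        order: tuple[int, int] = (0, 0),
        fit_intercept: bool = True,
        method: str = "REML",
    ):
        self.order = order
        self.fit_intercept = fit_intercept
        self.method = method

    # -- likelihood machinery -------------------------------------------------
    @staticmethod
    def _arma_corr(ar: np.ndarray, ma: np.ndarray, n: int) -> np.ndarray:
        acov = arma_acovf(np.r_[1.0, -ar], np.r_[1.0, ma], nobs=n)
        return linalg.toeplitz(acov / acov[0])

    def _constrain(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p, q = self.order
        ar = constrain_stationary_univariate(u[:p]) if p else np.empty(0)
        ma = constrain_stationary_univariate(u[p:]) if q else np.empty(0)
        return np.asarray(ar, float), np.asarray(ma, float)

    def _profile(self, u, X, y):
        """Profile negative (restricted) log-likelihood and GLS quantities."""
        ar, ma = self._constrain(np.asarray(u, float))
        n, k = X.shape
        corr = self._arma_corr(ar, ma, n)
        L = linalg.cholesky(corr, lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < k:
            raise np.linalg.LinAlgError("singular design matrix (constant predictor?)")
        rw = yw - Xw @ beta
        rss = float(rw @ rw)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        if self.method == "REML":
            m = n - k
            sigma2 = rss / m
            _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
            nll = 0.5 * (m * np.log(2.0 * np.pi * sigma2) + logdet + logdet_xx + m)
        else:
            sigma2 = rss / n
            nll = 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return nll, beta, rss, Xw, ar, ma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(y):
            raise ValueError("X and y lengths differ")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values must be removed before fitting")
        p, q = self.order
        if p < 0 or q < 0:
            raise ValueError("ARMA orders must be nonnegative")
        if self.method not in ("REML", "ML"):
            raise ValueError(f"unknown method {self.method!r}")
        n = len(y)
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        k = design.shape[1]
        if n <= k:
            raise ValueError("need more observations than coefficients")

        if p + q == 0:
            u_opt = np.empty(0)
        else:
            def objective(u):
                try:
                    return self._profile(u, design, y)[0]
                except (np.linalg.LinAlgError, linalg.LinAlgError):
                    return np.inf

            res = optimize.minimize(
                objective,
                x0=np.zeros(p + q),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            u_opt = res.x

        nll, beta, rss, Xw, ar, ma = self._profile(u_opt, design, y)
        dof = n - k
        sigma2_hat = rss / dof
        cov = sigma2_hat * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)

        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.ar_ = ar
        self.ma_ = ma
        self.sigma_ = float(np.sqrt(sigma2_hat))
        self.params_cov_ = cov
        self.params_se_ = se
        self.pvalues_ = pvals
        self.loglik_ = -nll
        self.n_obs_ = n
        self.dof_resid_ = dof
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


def gls_arma(
    pair: AlignedPair | tuple, order: tuple[int, int], method: str = "REML"
) -> GLSFit:
    """Fit ``response = intercept + slope * predictor`` with ARMA(p,q) errors.

    ``pair`` is an :class:`AlignedPair` or a plain ``(response, predictor)``
    tuple.  Returns the slope test, the residual standard error and the
    correlation between the intercept and slope estimators (the quantity
    reported in the result tables).
    """
    if isinstance(pair, AlignedPair):
        y, x = pair.response, pair.predictor
    else:
        y, x = np.asarray(pair[0], float), np.asarray(pair[1], float)
    est = ArmaGLS(order=tuple(order), method=method).fit(x[:, None], y)
    cov = est.params_cov_
    est_corr = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    return GLSFit(
        intercept=est.intercept_,
        slope=float(est.coef_[0]),
        intercept_se=float(est.params_se_[0]),
        slope_se=float(est.params_se_[1]),
        slope_p=float(est.pvalues_[1]),
        residual_std_error=est.sigma_,
        order=tuple(order),
        ar=est.ar_,
        ma=est.ma_,
        estimate_correlation=est_corr,
        n=est.n_obs_,
        loglik=est.loglik_,
    )


# ---------------------------------------------------------------------------
# the full decision pipeline

class PipelineStageError(RuntimeError):
    """An error raised by a named stage of the correlation pipeline."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches of the correlation procedure.

    ``alpha`` is used throughout with p <= alpha counted significant.
    ``trigger_combine`` decides when to difference: ``"and"`` (default)
    requires a significant time trend and serious autocorrelation together,
    ``"or"`` differences on either.  ``dw_on`` selects the residuals the
    autocorrelation check runs on: the response~predictor regression
    (default) or the response~time regression.
    """

    alpha: float = 0.05
    trigger_combine: str = "and"
    dw_bounds: tuple[float, float] = (1.5, 2.5)
    dw_on: str = "response_vs_predictor"
    max_p: int = 2
    max_q: int = 2
    max_d: int = 5
    min_pairs: int = 4


@dataclass
class PipelineResult:
    """One row of the correlation report plus the underlying diagnostics."""

    label: str
    lag: int
    order: tuple[int, int, int]
    slope: float
    slope_p: float
    estimate_correlation: float
    residual_std_error: float
    differenced: bool
    n: int
    trend_response: TrendDiagnostics | None = None
    trend_predictor: TrendDiagnostics | None = None
    autocorr: AutocorrDiagnostics | None = None
    ndiffs_check: int | None = None
    gls: GLSFit | None = None

    def as_row(self) -> dict:
        p, d, q = self.order
        return {
            "group": self.label,
            "lag": self.lag,
            "p": p,
            "d": d,
            "q": q,
            "slope": self.slope,
            "p_value": self.slope_p,
            "correlation": self.estimate_correlation,
            "residual_std_error": self.residual_std_error,
            "differenced": self.differenced,
            "n": self.n,
        }


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(x)), x])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise np.linalg.LinAlgError("constant predictor; OLS residuals undefined")
    return y - X @ beta


def run_correlation_pipeline(
    response,
    predictor,
    lag: int = 0,
    config: PipelineConfig = PipelineConfig(),
    label: str = "",
) -> PipelineResult:
    """Run the full trend / autocorrelation / ARIMA / GLS decision procedure.

    ``response`` and ``predictor`` are level-indexed series (pandas Series
    sharing an index, or equal-length arrays).  Every decision taken
    (differencing, selected order) is logged at info level; stage failures
    raise :class:`PipelineStageError` naming the stage.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    # missing-row deletion (lag 0 view used for trend/diagnostic stages)
    clean0 = _stage("align_and_clean", align_and_clean, response, predictor, 0,
                    config.min_pairs)
    y_c, x_c = clean0.response, clean0.predictor

    def _trends():
        if np.ptp(y_c) == 0 and np.ptp(x_c) == 0:
            raise ValueError("both series are constant; no correlation is defined")
        return trend_tests(y_c), trend_tests(x_c)

    trend_y, trend_x = _stage("trend_tests", _trends)
    trend_sig = trend_y.significant(config.alpha) or trend_x.significant(config.alpha)

    pair = _stage("align_and_clean", align_and_clean, y_c, x_c, lag, config.min_pairs)

    def _autocorr():
        if config.dw_on == "response_vs_time":
            resid = _ols_residuals(y_c, np.arange(len(y_c), dtype=float))
        else:
            resid = _ols_residuals(pair.response, pair.predictor)
        return autocorr_diagnostics(resid)

    ac = _stage("autocorr_diagnostics", _autocorr)
    serious = ac.serious(config.dw_bounds)

    if config.trigger_combine == "and":
        differenced = trend_sig and serious
    elif config.trigger_combine == "or":
        differenced = trend_sig or serious
    else:
        raise ValueError(f"unknown trigger_combine {config.trigger_combine!r}")
    logger.info(
        "%s lag %d: trend significant=%s (p_resp=%.3g, p_pred=%.3g), "
        "serious autocorrelation=%s (DW=%.2f) -> differenced=%s",
        label or "series", lag, trend_sig, trend_y.ols_p, trend_x.ols_p,
        serious, ac.durbin_watson, differenced,
    )

    if differenced:
        y_use = _stage("generalized_difference", generalized_difference, y_c)
        x_use = _stage("generalized_difference", generalized_difference, x_c)
        pair = _stage("align_and_clean", align_and_clean, y_use, x_use, lag,
                      config.min_pairs)

    resid = _stage("ols_residuals", _ols_residuals, pair.response, pair.predictor)
    arima = _stage("auto_arima", auto_arima, resid, config.max_p, config.max_q,
                   None, config.max_d, config.alpha)
    check_d = _stage("ndiffs", ndiffs, arima.resid, config.max_d, config.alpha)

    # A positive unit-root outcome (either within the order selection or in
    # the post-fit stationarity confirmation) means the GLS cannot proceed on
    # the raw series: detrend both by generalized differencing and reselect.
    if (arima.order[1] > 0 or check_d > 0) and not differenced:
        logger.info(
            "%s lag %d: unit-root outcome positive (d=%d, confirmation d=%d); "
            "differencing both series",
            label or "series", lag, arima.order[1], check_d,
        )
        differenced = True
        y_use = _stage("generalized_difference", generalized_difference, y_c)
        x_use = _stage("generalized_difference", generalized_difference, x_c)
        pair = _stage("align_and_clean", align_and_clean, y_use, x_use, lag,
                      config.min_pairs)
        resid = _stage("ols_residuals", _ols_residuals, pair.response, pair.predictor)
        arima = _stage("auto_arima", auto_arima, resid, config.max_p, config.max_q,
                       0, config.max_d, config.alpha)
        check_d = _stage("ndiffs", ndiffs, arima.resid, config.max_d, config.alpha)
    if check_d > 0:
        logger.warning("%s lag %d: ARIMA residuals still suggest d=%d", label, lag, check_d)
    logger.info("%s lag %d: selected ARIMA order %s (AICc=%.2f)",
                label or "series", lag, arima.order, arima.aicc)

    p, d, q = arima.order
    fit = _stage("gls_arma", gls_arma, pair, (p, q))
    return PipelineResult(
        label=label,
        lag=lag,
        order=arima.order,
        slope=fit.slope,
        slope_p=fit.slope_p,
        estimate_correlation=fit.estimate_correlation,
        residual_std_error=fit.residual_std_error,
        differenced=differenced,
        n=pair.n,
        trend_response=trend_y,
        trend_predictor=trend_x,
        autocorr=ac,
        ndiffs_check=check_d,
        gls=fit,
    )
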