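"""Relationship-verification battery between arrivals and the search index.

Before the index is admitted as a predictor, its association with
arrivals is checked four ways on the training window:

* Pearson correlation with a two-sided t-test (on the untransformed,
  min-max normalized series);
* augmented Dickey-Fuller stationarity tests on each log series;
* the Johansen trace test for cointegration of the log pair;
* Granger causality (does the lagged log index improve an autoregression
  of log arrivals?).

The Johansen deterministic specification used here is a constant in the
cointegrating relation with no trend (``det_order=0``), and the Granger
lag order is selected by AIC over 1..7 weeks unless fixed by the caller;
both choices are recorded in the report so results stay interpretable.
Pearson/ADF delegate to scipy/statsmodels; the Granger F-test is computed
directly from the restricted and augmented least-squares fits so that the
large replication studies in the test-suite stay cheap.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.vector_ar.vecm import coint_johansen

from .weekly import WeeklySeries


class DegenerateSeriesError(ValueError):
    """A test cannot run on the given input (constant, collinear, too short)."""


@dataclass
class AdfResult:
    statistic: float
    p: float
    lags_used: int
    stationary_at_05: bool


@dataclass
class JohansenResult:
    trace_r0: float
    trace_r1: float
    crit_r0: dict[str, float]  # keys "10%", "5%", "1%"
    crit_r1: dict[str, float]
    spec: str
    cointegrated_at_05: bool
    cointegrated_at_01: bool


@dataclass
class GrangerResult:
    f_statistic: float
    p: float
    lag: int
    degenerate: bool = False


@dataclass
class RelationshipReport:
    """Complete validation output; every field either filled or marked degenerate."""

    pearson_r: float
    pearson_p: float
    adf_arrivals: AdfResult
    adf_index: AdfResult
    johansen: JohansenResult
    granger_index_to_arrivals: GrangerResult
    granger_arrivals_to_index: GrangerResult
    log_transform: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def pearson_test(x: WeeklySeries, y: WeeklySeries) -> tuple[float, float]:
    """Pearson r between two aligned series with its two-sided p-value."""
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x.values) == 0 or np.std(y.values) == 0:
        raise DegenerateSeriesError("constant series have no defined correlation")
    r, p = stats.pearsonr(x.values, y.values)
    return float(r), float(p)


def adf_stationarity(series: WeeklySeries, regression: str = "c") -> AdfResult:
    """ADF unit-root test with a constant term and AIC lag selection.

    Rejection (small p) is evidence of stationarity around the chosen
    deterministic term.  A deterministic linear trend is *not* included by
    default; a trending series therefore tends to look nonstationary under
    this convention.
    """
    if len(series) < 12:
        raise ValueError("ADF needs at least 12 observations")
    stat, p, lags, *_ = adfuller(series.values, regression=regression, autolag="AIC")
    return AdfResult(float(stat), float(p), int(lags), bool(p <= 0.05))


def johansen_trace(
    x: WeeklySeries,
    y: WeeklySeries,
    log: bool = False,
    k_ar_diff: int = 1,
) -> JohansenResult:
    """Bivariate Johansen trace test (constant, no trend; ``det_order=0``).

    Reports the trace statistics for the nulls rank = 0 and rank <= 1 with
    their tabulated 10/5/1% critical values, and cointegration verdicts
    (both nulls rejected) at the 5% and 1% levels.
    """
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 20:
        raise ValueError("Johansen test needs at least 20 observations")
    xv, yv = x.values.astype(float), y.values.astype(float)
    if log:
        if (xv <= 0).any() or (yv <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        xv, yv = np.log(xv), np.log(yv)
    data = np.column_stack([xv, yv])
    resid = data - data.mean(axis=0)
    # A (near-)collinear pair makes the VECM system singular.
    s = np.linalg.svd(resid, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        raise DegenerateSeriesError("the two series are collinear; the system is singular")
    res = coint_johansen(data, det_order=0, k_ar_diff=k_ar_diff)
    levels = ["10%", "5%", "1%"]
    crit_r0 = dict(zip(levels, map(float, res.trace_stat_crit_vals[0])))
    crit_r1 = dict(zip(levels, map(float, res.trace_stat_crit_vals[1])))
    tr0, tr1 = map(float, res.trace_stat)
    return JohansenResult(
        trace_r0=tr0,
        trace_r1=tr1,
        crit_r0=crit_r0,
        crit_r1=crit_r1,
        spec="unrestricted constant, no trend (det_order=0)",
        # Rejecting rank 0 is evidence of >= 1 cointegrating relation.
        cointegrated_at_05=bool(tr0 > crit_r0["5%"]),
        cointegrated_at_01=bool(tr0 > crit_r0["1%"]),
    )


def _lagmat(v: np.ndarray, lags: int) -> np.ndarray:
    """Columns v[t-1], ..., v[t-lags] for t = lags..n-1."""
    return np.column_stack([v[lags - k : len(v) - k] for k in range(1, lags + 1)])


def _granger_at_lag(cause: np.ndarray, effect: np.ndarray, lag: int):
    """Restricted vs augmented OLS; returns (F, p, rss_aug, n_obs, k_aug)."""
    y = effect[lag:]
    n_obs = len(y)
    X_r = np.column_stack([np.ones(n_obs), _lagmat(effect, lag)])
    X_a = np.column_stack([X_r, _lagmat(cause, lag)])
    beta_r, *_ = np.linalg.lstsq(X_r, y, rcond=None)
    beta_a, *_ = np.linalg.lstsq(X_a, y, rcond=None)
    rss_r = float(np.sum((y - X_r @ beta_r) ** 2))
    rss_a = float(np.sum((y - X_a @ beta_a) ** 2))
    df_denom = n_obs - X_a.shape[1]
    if df_denom <= 0:
        raise ValueError("not enough observations for this lag order")
    if rss_a <= 0:
        return 0.0, 1.0, rss_a, n_obs, X_a.shape[1], True
    f = max((rss_r - rss_a) / lag / (rss_a / df_denom), 0.0)
    p = float(stats.f.sf(f, lag, df_denom))
    return float(f), p, rss_a, n_obs, X_a.shape[1], False


def granger_causality(
    cause: WeeklySeries,
    effect: WeeklySeries,
    max_lag: int = 7,
    lag: Optional[int] = None,
) -> GrangerResult:
    """Does past ``cause`` improve an autoregression of ``effect``?

    The F-test compares the restricted AR(lag) model of ``effect``
    against the model augmented with ``lag`` lags of ``cause``.  With
    ``lag=None`` the order is chosen by Gaussian AIC of the *restricted*
    autoregression (on the common sample implied by ``max_lag``): under
    the no-causality null the selection then never looks at ``cause``,
    which keeps the size of the subsequent F-test at its nominal level.
    """
    if len(cause) != len(effect):
        raise ValueError("series must have equal length")
    if len(effect) < 4 * max(max_lag, lag or 1):
        raise ValueError("series too short for the requested lag order")
    c, e = cause.values.astype(float), effect.values.astype(float)
    if np.std(c) == 0:
        return GrangerResult(f_statistic=0.0, p=1.0, lag=lag or 1, degenerate=True)

    if lag is None:
        best = None
        y = e[max_lag:]
        n_obs = len(y)
        for k in range(1, max_lag + 1):
            X = np.column_stack(
                [np.ones(n_obs), _lagmat(e, max_lag)[:, :k]]
            )
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            aic = n_obs * np.log(max(rss, 1e-300) / n_obs) + 2 * (k + 1)
            if best is None or aic < best[0]:
                best = (aic, k)
        lag = best[1]

    f, p, _, _, _, degen = _granger_at_lag(c, e, lag)
    return GrangerResult(f, p, lag, degen)


def validate(
    arrivals: WeeklySeries,
    index: WeeklySeries,
    max_lag: int = 7,
    granger_lag: Optional[int] = None,
) -> RelationshipReport:
    """Run the full battery on aligned (typically training-window) series.

    Pearson runs on min-max normalized raw series; ADF, Johansen and
    Granger run on the log-transformed series to damp outliers, matching
    the convention of reporting the long-run relationship in logs.
    """
    if len(arrivals) != len(index):
        raise ValueError("arrivals and index must be aligned to the same weeks")

    def _minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise DegenerateSeriesError("constant series")
        return (v - lo) / (hi - lo)

    r, p = stats.pearsonr(_minmax(arrivals.values), _minmax(index.values))

    if (arrivals.values <= 0).any() or (index.values <= 0).any():
        raise ValueError("log transform requires strictly positive series")
    log_arr = WeeklySeries(arrivals.week_start, np.log(arrivals.values), "log_arrivals")
    log_idx = WeeklySeries(index.week_start, np.log(index.values), "log_index")

    return RelationshipReport(
        pearson_r=float(r),
        pearson_p=float(p),
        adf_arrivals=adf_stationarity(log_arr),
        adf_index=adf_stationarity(log_idx),
        johansen=johansen_trace(log_arr, log_idx),
        granger_index_to_arrivals=granger_causality(
            log_idx, log_arr, max_lag=max_lag, lag=granger_lag
        ),
        granger_arrivals_to_index=granger_causality(
            log_arr, log_idx, max_lag=max_lag, lag=granger_lag
        ),
        log_transform=True,
    )
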