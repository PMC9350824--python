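"""Forecast accuracy metrics, the Diebold-Mariano test, and robustness.

Point accuracy is summarized by MAPE and RMSE,

    MAPE = (100/N) sum_i |y_i - yhat_i| / y_i,
    RMSE = sqrt((1/N) sum_i (y_i - yhat_i)^2),

together with the count of *mismatch weeks* -- weeks whose absolute
percentage error strictly exceeds 18%, the staffing-reconfiguration
threshold used in ED practice.

Pairwise accuracy is compared with the Diebold-Mariano statistic on the
squared-error loss differential d_i = (y_i - yhat_re,i)^2 -
(y_i - yhat_te,i)^2,

    DM = dbar / sqrt((gamma_0 + 2 sum_{k=1}^{h-1} gamma_k) / N),

with gamma_k the lag-k autocovariance of d.  The null is that the
*reference* model is at least as accurate as the *test* model (E[d] <= 0);
the one-sided p-value comes from the standard normal upper tail (the
small-sample Harvey correction is available but off by default).  Tables
of all pairwise comparisons share one Benjamini-Hochberg FDR family.

Robustness re-runs the full pipeline on expanding data windows of
different lengths and reports the SD of test MAPE and RMSE per model and
predictor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetricReport:
    mape: float  # percent
    rmse: float  # units of the target
    n: int
    mismatch_weeks: int

    def to_dict(self) -> dict:
        return {
            "mape": self.mape,
            "rmse": self.rmse,
            "n": self.n,
            "mismatch_weeks": self.mismatch_weeks,
        }


def compute_metrics(
    actual: np.ndarray, predicted: np.ndarray, mismatch_threshold: float = 0.18
) -> MetricReport:
    """MAPE (%), RMSE and the mismatch-week count at the given threshold.

    Every actual value must be strictly positive (MAPE is undefined at 0);
    a week is a mismatch iff its absolute percentage error is *strictly*
    above the threshold.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("actual and predicted must be equal-length nonempty 1-D arrays")
    if (y == 0).any():
        raise ValueError("MAPE is undefined when an actual value is 0")
    ape = np.abs(y - yhat) / np.abs(y)
    return MetricReport(
        mape=float(100.0 * ape.mean()),
        rmse=float(np.sqrt(np.mean((y - yhat) ** 2))),
        n=len(y),
        mismatch_weeks=int(np.sum(ape > mismatch_threshold)),
    )


def squared_error(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    return (y - yhat) ** 2


def absolute_error(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    return np.abs(y - yhat)


_LOSSES: dict[str, Callable] = {"squared_error": squared_error, "absolute_error": absolute_error}


@dataclass
class DMResult:
    statistic: float
    p: float  # one-sided: small p favours the test model over the reference
    h: int
    loss: str
    d_series: np.ndarray
    stationarity_p: Optional[float] = None
    degenerate: bool = False
    p_fdr: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "h": self.h,
            "loss": self.loss,
            "degenerate": self.degenerate,
            "stationarity_p": self.stationarity_p,
        }


def _autocovariance(d: np.ndarray, k: int) -> float:
    n = len(d)
    dc = d - d.mean()
    return float(np.sum(dc[k:] * dc[: n - k]) / n)


def dm_test(
    actual: np.ndarray,
    pred_reference: np.ndarray,
    pred_test: np.ndarray,
    h: int = 1,
    loss: str = "squared_error",
    harvey_correction: bool = False,
    adf_on_d: bool = False,
) -> DMResult:
    """Diebold-Mariano comparison of two forecast series on the same weeks.

    ``d_i = loss(y_i, ref_i) - loss(y_i, test_i)``; large positive DM
    means the test model is more accurate.  An identically-zero (or
    zero-variance) differential returns statistic 0, p 0.5 and a
    degeneracy flag instead of dividing by zero.
    """
    y = np.asarray(actual, dtype=float)
    f_re = np.asarray(pred_reference, dtype=float)
    f_te = np.asarray(pred_test, dtype=float)
    if not (y.shape == f_re.shape == f_te.shape) or y.ndim != 1:
        raise ValueError("all three series must be equal-length 1-D arrays")
    n = len(y)
    if n < 8:
        raise ValueError("DM test needs at least 8 forecasts")
    if h < 1:
        raise ValueError("h must be >= 1")
    if loss not in _LOSSES:
        raise ValueError(f"unknown loss {loss!r}")
    loss_fn = _LOSSES[loss]
    d = loss_fn(y, f_re) - loss_fn(y, f_te)

    lrv = _autocovariance(d, 0) + 2.0 * sum(_autocovariance(d, k) for k in range(1, h))
    stat_p: Optional[float] = None
    if adf_on_d and np.ptp(d) > 0:
        from statsmodels.tsa.stattools import adfuller

        try:
            stat_p = float(adfuller(d, regression="c", autolag="AIC")[1])
        except Exception:
            stat_p = None

    if lrv <= 0:
        return DMResult(0.0, 0.5, h, loss, d, stat_p, degenerate=True)
    dm = float(d.mean() / np.sqrt(lrv / n))
    if harvey_correction:
        corr = np.sqrt((n + 1 - 2 * h + h * (h - 1) / n) / n)
        dm *= corr
        p = float(stats.t.sf(dm, df=n - 1))
    else:
        p = float(stats.norm.sf(dm))
    return DMResult(dm, p, h, loss, d, stat_p)


def pairwise_dm_table(
    actual: np.ndarray,
    predictions: dict[str, np.ndarray],
    h: int = 1,
    loss: str = "squared_error",
    alpha: float = 0.05,
) -> dict[tuple[str, str], DMResult]:
    """All ordered pairwise DM comparisons with one joint FDR family.

    ``predictions`` maps model name to its forecasts on the shared test
    weeks.  Every ordered pair (reference, test) is computed, but the BH
    family contains one p-value per *unordered* pair, taken in input
    order (earlier model as reference); the reversed orientation carries
    the exactly negated statistic and its own raw p (= 1 - p of the
    canonical orientation) with no separate adjusted value.
    """
    from .index import fdr_adjust

    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    n_ref = len(np.asarray(actual))
    for name, pred in predictions.items():
        if len(np.asarray(pred)) != n_ref:
            raise ValueError(f"predictions for {name!r} are not on the shared test weeks")

    table: dict[tuple[str, str], DMResult] = {}
    family_pairs: list[tuple[str, str]] = []
    for i, ref in enumerate(names):
        for te in names[i + 1 :]:
            table[(ref, te)] = dm_test(actual, predictions[ref], predictions[te], h=h, loss=loss)
            table[(te, ref)] = dm_test(actual, predictions[te], predictions[ref], h=h, loss=loss)
            family_pairs.append((ref, te))

    adjusted = fdr_adjust([table[pair].p for pair in family_pairs])
    for pair, p_adj in zip(family_pairs, adjusted):
        table[pair].p_fdr = float(p_adj)
    return table


@dataclass
class RobustnessReport:
    """SDs of test accuracy across expanding-window re-runs."""

    sd_mape: dict[str, float]  # key "model/set" -> SD of test MAPE (percent)
    sd_rmse: dict[str, float]
    lengths: list[int]
    per_run: dict[str, list[dict]] = field(default_factory=dict)
    flagged_runs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sd_mape": self.sd_mape,
            "sd_rmse": self.sd_rmse,
            "lengths": self.lengths,
            "per_run": self.per_run,
            "flagged_runs": self.flagged_runs,
        }


def expanding_length_schedule(n_weeks: int, n_runs: int = 20) -> list[int]:
    """Expanding-window lengths with endpoints spread over the final third."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    lo = int(np.ceil(2 * n_weeks / 3))
    return [int(round(v)) for v in np.linspace(lo, n_weeks, n_runs)]


def robustness_sd(per_run_metrics: Sequence[MetricReport]) -> tuple[float, float]:
    """Sample SDs (ddof=1) of MAPE and RMSE across runs."""
    if len(per_run_metrics) < 2:
        raise ValueError("robustness needs at least 2 runs")
    mapes = [m.mape for m in per_run_metrics]
    rmses = [m.rmse for m in per_run_metrics]
    return float(np.std(mapes, ddof=1)), float(np.std(rmses, ddof=1))


def robustness_analysis(
    scenario,
    models: Sequence[str] = ("elm", "glm"),
    predictor_sets: Sequence[str] = ("traditional", "index"),
    n_runs: int = 20,
    train_weeks: int = 27,
    lengths: Optional[Sequence[int]] = None,
    model_seed: int = 0,
) -> RobustnessReport:
    """Re-run the pipeline on expanding windows and report accuracy SDs.

    ``scenario`` is an (arrivals, covariates, panel) bundle.  Each run
    truncates it to a scheduled length (endpoints evenly spread over the
    final third by default), re-screens the index on the run's training
    window, refits every model, and records test MAPE/RMSE; the report
    holds the SD per model and predictor set.  A run in which screening
    selects nothing falls back to the no-index sets and is flagged, never
    dropped silently.
    """
    from .pipeline import run_pipeline, truncate_scenario

    n_weeks = len(scenario[0])
    if lengths is None:
        lengths = expanding_length_schedule(n_weeks, n_runs)
    lengths = [int(v) for v in lengths]
    if len(lengths) < 2:
        raise ValueError("robustness needs at least 2 runs")
    for length in lengths:
        if length <= train_weeks:
            raise ValueError(f"scheduled length {length} does not admit the split")

    per_run: dict[str, list[dict]] = {}
    collected: dict[str, list[MetricReport]] = {}
    flagged: list[dict] = []
    for run_id, length in enumerate(lengths):
        sub = truncate_scenario(scenario, length)
        result = run_pipeline(
            scenario=sub,
            train_weeks=train_weeks,
            models=models,
            predictor_sets=predictor_sets,
            model_seed=model_seed,
            run_validation=False,
        )
        if result.flags:
            flagged.append({"run": run_id, "length": length, "flags": result.flags})
        for (model, pset), res in result.forecasts.items():
            key = f"{model}/{pset}"
            m = res.metrics("test")
            collected.setdefault(key, []).append(m)
            per_run.setdefault(key, []).append(
                {"run": run_id, "length": length, "mape": m.mape, "rmse": m.rmse}
            )

    sd_mape, sd_rmse = {}, {}
    for key, ms in collected.items():
        if len(ms) >= 2:
            sd_mape[key], sd_rmse[key] = robustness_sd(ms)
    return RobustnessReport(
        sd_mape=sd_mape, sd_rmse=sd_rmse, lengths=lengths, per_run=per_run, flagged_runs=flagged
    )
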