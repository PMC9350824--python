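"""Synthetic weekly ED-arrival scenarios with a leading search-query panel.

The generator emulates the statistical structure the downstream analysis
assumes in an H1N1-era Hong Kong setting: about one year of weekly average
daily ED arrivals centred near 380, with monthly seasonality (winter and
mid-summer peaks), holiday and temperature effects, sharp epidemic bursts,
and AR(1) noise; alongside it, a Google-Trends-like panel of search-query
series (0-100 normalized) in which a small planted subset *leads* arrivals
by 1-7 weeks while the remainder is pure autocorrelated noise.

Planted queries carry the scenario's epidemic + seasonal signal read
``lag`` weeks ahead, plus white noise whose scale is calibrated so that the
population Pearson correlation between the lag-shifted query and arrivals,
over the screening window, equals the configured target.  Ground truth for
every planting (name, lag, signed effect) travels with the panel so that
screening-recovery experiments need no bookkeeping outside the scenario.

All randomness flows from a single master seed through per-component
substreams (temperatures, arrival noise, holidays, one stream per query),
so changing the query count never perturbs the arrivals series.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .weekly import Planting, QueryPanel, TraditionalCovariates, WeeklySeries


class ConfigurationError(ValueError):
    """A SyntheticConfig invariant is violated; names the offending field."""

    def __init__(self, fld: str, message: str) -> None:
        self.field = fld
        super().__init__(f"SyntheticConfig.{fld}: {message}")


# January..December additive effects on average daily arrivals; winter
# (Jan) and mid-summer (Jul) peaks mirror the bimodal pattern typical of
# subtropical ED demand.
_DEFAULT_MONTH_EFFECTS = (25.0, 5.0, -10.0, -15.0, -10.0, 0.0, 30.0, 10.0, -5.0, -10.0, 0.0, 15.0)

# Table-2-like signed target correlations and lead lags for the planted
# queries (nine queries, lags drawn from {1, 2, 6, 7}, |r| in 0.31..0.50).
_DEFAULT_PLANTED_LAGS = (1, 1, 1, 1, 2, 2, 2, 6, 7)
_DEFAULT_PLANTED_EFFECTS = (-0.33, 0.50, 0.36, 0.43, 0.31, 0.49, -0.32, 0.38, -0.42)


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario parameters; defaults reproduce the analysis's study conditions.

    Attributes
    ----------
    n_weeks : total length of the weekly grid (>= 16 so a 27/24-style
        split remains meaningful at default size).
    start_date : ISO date of the first week's Sunday.
    baseline_mean : average daily arrivals in a plain week.
    month_effects : twelve additive offsets, January..December.
    public_holiday_effect, school_holiday_effect : additional average
        daily arrivals per holiday day in the week.
    temp_slope : arrivals per degree C of weekly low-temperature deviation
        from its annual mean (negative: cold weeks are busier).
    epidemic_bursts : Gaussian pulses ``(center_week, width_weeks, height)``
        added to arrivals; the default pair stands for a large first wave
        inside the training window and a smaller later outbreak in the
        test window.
    ar_coef, noise_sd : AR(1) coefficient and innovation SD of the
        arrivals noise.
    n_queries, n_planted : panel size and number of signal-carrying queries.
    planted_lags, planted_effects : per-planting lead (weeks, 1..7) and
        signed target population correlation.
    query_noise_sd : SD floor of the white noise added to planted queries
        before calibration (calibration may only widen it).
    query_ar : AR(1) coefficient of the non-planted noise queries.
    calibration_weeks : screening window (first k weeks) over which planted
        correlations are calibrated to their targets.
    seed : master RNG seed.
    """

    n_weeks: int = 51
    start_date: str = "2009-07-12"
    baseline_mean: float = 380.0
    month_effects: Sequence[float] = _DEFAULT_MONTH_EFFECTS
    public_holiday_effect: float = 6.0
    school_holiday_effect: float = 2.0
    temp_slope: float = -1.2
    temp_mean_high: float = 27.0
    temp_amplitude: float = 5.0
    temp_gap: float = 5.0
    temp_noise_sd: float = 1.0
    epidemic_bursts: Sequence[tuple[float, float, float]] = ((18.0, 1.5, 80.0), (40.0, 2.0, 45.0))
    ar_coef: float = 0.45
    noise_sd: float = 8.0
    n_queries: int = 268
    n_planted: int = 9
    planted_lags: Sequence[int] = _DEFAULT_PLANTED_LAGS
    planted_effects: Sequence[float] = _DEFAULT_PLANTED_EFFECTS
    query_noise_sd: float = 0.0
    query_ar: float = 0.3
    calibration_weeks: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 16:
            raise ConfigurationError("n_weeks", "must be >= 16")
        if len(tuple(self.month_effects)) != 12:
            raise ConfigurationError("month_effects", "must list 12 monthly offsets")
        for fld in ("noise_sd", "temp_noise_sd", "query_noise_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(fld, "standard deviations must be >= 0")
        if not (0 <= abs(self.ar_coef) < 1):
            raise ConfigurationError("ar_coef", "must satisfy |coef| < 1")
        if not (0 <= abs(self.query_ar) < 1):
            raise ConfigurationError("query_ar", "must satisfy |coef| < 1")
        if self.n_planted > self.n_queries:
            raise ConfigurationError("n_planted", "cannot exceed n_queries")
        if len(tuple(self.planted_lags)) != self.n_planted:
            raise ConfigurationError("planted_lags", f"must list {self.n_planted} lags")
        if len(tuple(self.planted_effects)) != self.n_planted:
            raise ConfigurationError("planted_effects", f"must list {self.n_planted} effects")
        for lag in self.planted_lags:
            if not (1 <= int(lag) <= 7):
                raise ConfigurationError("planted_lags", "lags must lie in 1..7")
        for eff in self.planted_effects:
            if not (0 < abs(eff) <= 1):
                raise ConfigurationError("planted_effects", "effects must satisfy 0 < |r| <= 1")
        if not (8 <= self.calibration_weeks <= self.n_weeks):
            raise ConfigurationError("calibration_weeks", "must lie in 8..n_weeks")
        for burst in self.epidemic_bursts:
            if len(burst) != 3 or burst[1] <= 0:
                raise ConfigurationError(
                    "epidemic_bursts", "each burst is (center_week, width>0, height)"
                )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "epidemic_bursts" in raw:
            raw["epidemic_bursts"] = tuple(tuple(b) for b in raw["epidemic_bursts"])
        return cls(**raw)


def _week_grid(config: SyntheticConfig, n: Optional[int] = None) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_date)
    return pd.DatetimeIndex([start + pd.Timedelta(days=7 * i) for i in range(n or config.n_weeks)])


def _pulse_path(config: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for center, width, height in config.epidemic_bursts:
        out += height * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _deterministic_paths(config: SyntheticConfig, n_ext: int):
    """Deterministic components on an extended grid (n_weeks + max lag).

    Returns (months, temp_high_det, temp_low_det, pub, sch, arrivals_det,
    signal) where ``signal`` is the epidemic + monthly-seasonal component
    the planted queries carry, and arrivals_det excludes all noise.
    Holiday placement is pseudo-random but drawn from its own substream in
    the caller; here only deterministic school blocks are produced.
    """
    grid = _week_grid(config, n_ext)
    months = grid.month.to_numpy()
    t = np.arange(n_ext, dtype=float)
    doy = grid.dayofyear.to_numpy(dtype=float)
    # Annual temperature cycle peaking in mid-July (subtropical).
    temp_high_det = config.temp_mean_high + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - 200.0) / 365.25
    )
    temp_low_det = temp_high_det - config.temp_gap
    month_eff = np.asarray(config.month_effects, dtype=float)[months - 1]
    pulses = _pulse_path(config, t)
    signal = month_eff + pulses
    return grid, months, temp_high_det, temp_low_det, month_eff, pulses, signal


def _school_holiday_days(config: SyntheticConfig, grid: pd.DatetimeIndex) -> np.ndarray:
    """Whole-week school closures: summer (Jul-Aug), winter (late Dec), spring (mid Feb)."""
    months = grid.month.to_numpy()
    days = grid.day.to_numpy()
    out = np.zeros(len(grid), dtype=int)
    out[(months == 7) | (months == 8)] = 7
    out[(months == 12) & (days >= 15)] = 7
    out[(months == 1) & (days <= 7)] = 7
    out[(months == 2) & (days >= 8) & (days <= 21)] = 7
    return out


def _public_holiday_days(rng: np.random.Generator, n: int) -> np.ndarray:
    """Scatter ~17 public-holiday days per year into weekly counts (0..3)."""
    n_days = max(1, round(17 * n / 52.18))
    weeks = rng.integers(0, n, size=n_days)
    counts = np.bincount(weeks, minlength=n)
    return np.minimum(counts, 3).astype(int)


def _calibrated_noise_scale(
    config: SyntheticConfig,
    lag: int,
    target_abs_r: float,
    signal_z: np.ndarray,
    arrivals_det: np.ndarray,
    arrivals_noise_var: float,
) -> float:
    """Solve for the white-noise SD giving the target lagged correlation.

    The screening pairs over the calibration window are
    ``(q[t-lag], arrivals[t])`` for t in [lag, calibration_weeks); with
    ``q[t-lag] = sign*z[t] + s*eps`` the expected Pearson correlation is
    ``cov_W(z, det) / sqrt((var_W(z) + s^2) (var_W(det) + noise_var))``,
    using across-window moments of the deterministic paths.  Returns the
    smallest s >= query_noise_sd matching the target (0 if the target is
    unreachable even noise-free).
    """
    w = slice(lag, config.calibration_weeks)
    z = signal_z[w]
    d = arrivals_det[w]
    cz = float(np.cov(z, d, bias=True)[0, 1])
    vz = float(np.var(z))
    vd = float(np.var(d)) + arrivals_noise_var
    s2 = (cz * cz) / (target_abs_r**2 * vd) - vz
    s2 = max(s2, config.query_noise_sd**2)
    return float(np.sqrt(max(s2, 0.0)))


def generate_scenario(
    config: SyntheticConfig,
) -> tuple[WeeklySeries, TraditionalCovariates, QueryPanel]:
    """Generate one scenario bundle: arrivals, covariates and query panel.

    Output is a pure function of ``config`` (which includes the seed):
    identical configs yield bit-identical arrays.
    """
    n = config.n_weeks
    max_lag = max([int(l) for l in config.planted_lags], default=0)
    n_ext = n + max_lag

    master = np.random.SeedSequence(config.seed)
    ss_temp, ss_arr, ss_hol, ss_queries = master.spawn(4)
    rng_temp = np.random.default_rng(ss_temp)
    rng_arr = np.random.default_rng(ss_arr)
    rng_hol = np.random.default_rng(ss_hol)
    query_streams = ss_queries.spawn(config.n_queries)

    grid_ext, months_ext, th_det, tl_det, month_eff, pulses, signal = _deterministic_paths(
        config, n_ext
    )
    grid = grid_ext[:n]

    # Covariates on the base grid.
    temp_noise_h = rng_temp.normal(0.0, config.temp_noise_sd, size=n)
    temp_noise = rng_temp.normal(0.0, config.temp_noise_sd, size=n)  # low-temperature shock
    temp_high = th_det[:n] + temp_noise_h
    temp_low = np.minimum(tl_det[:n] + temp_noise, temp_high - 0.5)
    pub = _public_holiday_days(rng_hol, n)
    sch = _school_holiday_days(config, grid)

    # Deterministic arrivals path (temperature noise counted as noise below).
    temp_dev = tl_det[:n] - tl_det[:n].mean()
    arrivals_det = (
        config.baseline_mean
        + signal[:n]
        + config.public_holiday_effect * pub
        + config.school_holiday_effect * sch
        + config.temp_slope * temp_dev
    )

    # AR(1) noise started from its stationary distribution.
    phi, sd = config.ar_coef, config.noise_sd
    stat_sd = sd / np.sqrt(1.0 - phi * phi) if sd > 0 else 0.0
    eps = rng_arr.normal(0.0, sd, size=n)
    noise = np.empty(n)
    noise[0] = rng_arr.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
    for i in range(1, n):
        noise[i] = phi * noise[i - 1] + eps[i]
    arrivals_vals = np.maximum(
        arrivals_det + config.temp_slope * temp_noise + noise, 0.0
    )
    arrivals = WeeklySeries(grid, arrivals_vals, "arrivals")

    covariates = TraditionalCovariates(
        week_start=grid,
        month=months_ext[:n],
        temp_high=temp_high,
        temp_low=temp_low,
        public_holidays=pub,
        school_holidays=sch,
    )

    # Query panel.  Planted queries sit at evenly spaced column positions.
    arrivals_noise_var = sd * sd / (1.0 - phi * phi) + (config.temp_slope * config.temp_noise_sd) ** 2
    sig_mean, sig_sd = float(signal.mean()), float(signal.std())
    signal_z = (signal - sig_mean) / sig_sd if sig_sd > 0 else np.zeros_like(signal)

    planted_idx = {
        int(np.floor(j * config.n_queries / max(config.n_planted, 1))): j
        for j in range(config.n_planted)
    }
    columns: dict[str, np.ndarray] = {}
    truth: list[Planting] = []
    for i in range(config.n_queries):
        name = f"q{i:03d}"
        rng_q = np.random.default_rng(query_streams[i])
        if i in planted_idx:
            j = planted_idx[i]
            lag = int(config.planted_lags[j])
            effect = float(config.planted_effects[j])
            scale = _calibrated_noise_scale(
                config, lag, abs(effect), signal_z, arrivals_det, arrivals_noise_var
            )
            raw = np.sign(effect) * signal_z[lag : lag + n] + rng_q.normal(0.0, scale, size=n)
            truth.append(Planting(query=name, lag=lag, effect=effect))
        else:
            qphi = config.query_ar
            innov = rng_q.normal(0.0, 1.0, size=n)
            raw = np.empty(n)
            raw[0] = innov[0] / np.sqrt(1.0 - qphi * qphi) if qphi else innov[0]
            for k in range(1, n):
                raw[k] = qphi * raw[k - 1] + innov[k]
        lo, hi = raw.min(), raw.max()
        columns[name] = (
            np.clip(100.0 * (raw - lo) / (hi - lo), 0.0, 100.0) if hi > lo else np.full(n, 50.0)
        )

    panel = QueryPanel(
        week_start=grid,
        queries=pd.DataFrame(columns, index=grid),
        truth=truth,
    )
    return arrivals, covariates, panel


# ---------------------------------------------------------------------------
# Serialization


def write_scenario(
    out_dir: str | Path,
    arrivals: WeeklySeries,
    covariates: TraditionalCovariates,
    panel: QueryPanel,
) -> None:
    """Write arrivals.csv, covariates.csv, panel.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iso = [d.strftime("%Y-%m-%d") for d in arrivals.week_start]

    pd.DataFrame({"week_start": iso, "arrivals": arrivals.values}).to_csv(
        out / "arrivals.csv", index=False
    )
    cov = covariates.to_pandas().reset_index(drop=True)
    cov.insert(0, "week_start", iso)
    cov.to_csv(out / "covariates.csv", index=False)
    pq = panel.queries.reset_index(drop=True)
    pq.insert(0, "week_start", iso)
    pq.to_csv(out / "panel.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            [{"query": p.query, "lag": p.lag, "effect": p.effect} for p in (panel.truth or [])],
            fh,
            indent=2,
        )
        fh.write("\n")


def read_scenario(
    in_dir: str | Path,
) -> tuple[WeeklySeries, TraditionalCovariates, QueryPanel]:
    """Inverse of :func:`write_scenario`."""
    src = Path(in_dir)
    arr = pd.read_csv(src / "arrivals.csv", parse_dates=["week_start"])
    grid = pd.DatetimeIndex(arr["week_start"])
    arrivals = WeeklySeries(grid, arr["arrivals"].to_numpy(), "arrivals")

    cov = pd.read_csv(src / "covariates.csv", parse_dates=["week_start"])
    covariates = TraditionalCovariates(
        week_start=pd.DatetimeIndex(cov["week_start"]),
        month=cov["month"].to_numpy(),
        temp_high=cov["temp_high"].to_numpy(),
        temp_low=cov["temp_low"].to_numpy(),
        public_holidays=cov["public_holidays"].to_numpy(),
        school_holidays=cov["school_holidays"].to_numpy(),
    )

    pq = pd.read_csv(src / "panel.csv", parse_dates=["week_start"])
    queries = pq.drop(columns=["week_start"])
    truth: Optional[list[Planting]] = None
    truth_path = src / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = [Planting(**rec) for rec in json.load(fh)]
    panel = QueryPanel(
        week_start=pd.DatetimeIndex(pq["week_start"]), queries=queries, truth=truth
    )
    return arrivals, covariates, panel
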