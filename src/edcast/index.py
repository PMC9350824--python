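"""Internet search-index construction: lagged screening and shift-and-sum.

A search query is useful as a leading indicator when its value ``lag``
weeks before a target week correlates with arrivals in that week.  The
construction has two stages:

1. *Screening* (:func:`select_queries`): for every query, Pearson
   correlations between ``q[t - lag]`` and ``arrivals[t]`` are computed for
   lag = 1..7 over the training window; the lag with the largest ``|r|``
   is kept, its two-sided p-value is Benjamini-Hochberg adjusted across
   queries, and a query is selected iff ``|r| >= threshold`` (default
   0.30) and the adjusted p is at most ``alpha`` (default .05).
2. *Fusion* (:func:`build_index`): each selected query is shifted forward
   by its best lag and the shifted series are summed into a single weekly
   index, defined from week ``max(lag)`` onward.

Negatively correlated queries enter the sum with their raw sign, and
:func:`build_index` performs an exact shift-and-sum; optional per-query
min-max weighting is applied by the pipeline before fusion so that no
single 0-100 query dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .weekly import QueryPanel, WeeklySeries


class EmptySelectionError(ValueError):
    """No query survived screening; callers fall back to the no-index set."""


@dataclass(frozen=True)
class LagSelection:
    """Screening outcome for one query."""

    query: str
    best_lag: int
    r: float
    p_raw: float
    p_fdr: float
    selected: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "lag": self.best_lag,
            "r": self.r,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "selected": self.selected,
        }


@dataclass
class SearchIndex:
    """The fused index series plus the (query, lag) pairs that built it."""

    series: WeeklySeries
    provenance: list[tuple[str, int]]
    start_week: int  # position on the panel grid where the index begins


def _resolve_window(n: int, window: Optional[tuple[int, int]]) -> tuple[int, int]:
    if window is None:
        return 0, n
    start, stop = window
    if not (0 <= start < stop <= n):
        raise ValueError(f"window {window!r} invalid for a series of length {n}")
    return start, stop


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r and two-sided t-distribution p; degenerate -> (0, 1, True)."""
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0, True
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, False
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), False


def lagged_pearson(
    query: WeeklySeries,
    arrivals: WeeklySeries,
    max_lag: int = 7,
    window: Optional[tuple[int, int]] = None,
) -> list[tuple[int, float, float]]:
    """Correlate ``query[t - lag]`` with ``arrivals[t]`` for lag = 1..max_lag.

    ``window`` restricts the target weeks t to positions [start, stop) on
    the shared grid (typically the training window); lagged query values
    may reach back before the window as long as they exist on the grid.

    Returns a list of ``(lag, r, p_raw)`` with p from the two-sided
    t-distribution test on ``pairs - 2`` degrees of freedom.  A constant
    overlap yields ``(lag, 0.0, 1.0)``.
    """
    if not query.same_grid(arrivals):
        raise ValueError("query and arrivals must share the same week grid")
    start, stop = _resolve_window(len(arrivals), window)
    if (stop - start) - max_lag < 3:
        raise ValueError("window too short: need >= 3 overlapping pairs at the largest lag")
    out = []
    for lag in range(1, max_lag + 1):
        t0 = max(start, lag)
        x = query.values[t0 - lag : stop - lag]
        y = arrivals.values[t0:stop]
        r, p, _ = _pearson_with_p(x, y)
        out.append((lag, r, p))
    return out


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_queries(
    panel: QueryPanel,
    arrivals: WeeklySeries,
    window: Optional[tuple[int, int]] = None,
    max_lag: int = 7,
    threshold: float = 0.30,
    alpha: float = 0.05,
) -> list[LagSelection]:
    """Screen every panel query by its best lagged correlation.

    Best lag is the argmax of ``|r|`` over lags (ties -> smallest lag);
    the BH adjustment runs across all queries' best-lag p-values jointly.
    Output is sorted by best lag, then by ``|r|`` descending.
    """
    if len(panel.names) == 0:
        return []
    if len(panel) != len(arrivals) or not (panel.week_start == arrivals.week_start).all():
        raise ValueError("panel and arrivals must share the same week grid")

    records = []
    for name in panel.names:
        per_lag = lagged_pearson(panel.column(name), arrivals, max_lag=max_lag, window=window)
        rs = np.array([r for _, r, _ in per_lag])
        degenerate = bool(np.all(rs == 0.0) and all(p == 1.0 for _, _, p in per_lag))
        best = int(np.argmax(np.abs(rs)))  # argmax returns the first (smallest) lag on ties
        lag, r, p_raw = per_lag[best]
        records.append((name, lag, r, p_raw, degenerate))

    p_fdr = fdr_adjust([rec[3] for rec in records])
    selections = []
    for (name, lag, r, p_raw, degenerate), p_adj in zip(records, p_fdr):
        selected = bool((not degenerate) and abs(r) >= threshold and p_adj <= alpha)
        selections.append(
            LagSelection(
                query=name,
                best_lag=int(lag),
                r=r,
                p_raw=p_raw,
                p_fdr=float(p_adj),
                selected=selected,
                degenerate=degenerate,
            )
        )
    selections.sort(key=lambda s: (s.best_lag, -abs(s.r)))
    return selections


def build_index(
    panel: QueryPanel,
    selections: Sequence[LagSelection],
    name: str = "search_index",
) -> SearchIndex:
    """Shift each selected query by its best lag and sum them exactly.

    ``index[t] = sum_j q_j[t - lag_j]`` for every t at or beyond the
    largest selected lag; earlier weeks are absent from the result.
    Raises :class:`EmptySelectionError` when nothing was selected.
    """
    chosen = [s for s in selections if s.selected]
    if not chosen:
        raise EmptySelectionError(
            "no query was selected; fall back to the predictor set without the index"
        )
    max_lag = max(s.best_lag for s in chosen)
    n = len(panel)
    values = np.zeros(n - max_lag)
    for s in chosen:
        q = panel.queries[s.query].to_numpy(dtype=float)
        values += q[max_lag - s.best_lag : n - s.best_lag]
    series = WeeklySeries(panel.week_start[max_lag:], values, name)
    return SearchIndex(
        series=series,
        provenance=[(s.query, s.best_lag) for s in chosen],
        start_week=max_lag,
    )


def normalize_panel(
    panel: QueryPanel, fit_window: Optional[tuple[int, int]] = None
) -> QueryPanel:
    """Min-max normalize each query column using ``fit_window`` statistics.

    Used before fusion so that every query contributes on a comparable
    scale; columns constant within the window are mapped to 0.5.  Values
    are clipped to [0, 1] (then rescaled to 0-100 to keep the panel
    contract) so out-of-window extremes cannot leave the valid range.
    """
    start, stop = _resolve_window(len(panel), fit_window)
    sub = panel.queries.iloc[start:stop]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)
    normed = ((panel.queries - lo) / span).fillna(0.5).clip(0.0, 1.0) * 100.0
    return QueryPanel(week_start=panel.week_start, queries=normed, truth=panel.truth)
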