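"""Screening and fusion: definition-level oracles, BH adjustment, and the
shift-and-sum index contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edcast.index import (
    EmptySelectionError,
    LagSelection,
    build_index,
    fdr_adjust,
    lagged_pearson,
    normalize_panel,
    select_queries,
)
from edcast.weekly import QueryPanel

from conftest import make_series


def _panel(columns: dict, start="2009-07-12"):
    grid = pd.DatetimeIndex(
        pd.date_range(start, periods=len(next(iter(columns.values()))), freq="7D")
    )
    return QueryPanel(week_start=grid, queries=pd.DataFrame(columns, index=grid))


# ---------------------------------------------------------------------------
# lagged_pearson


def test_perfect_lagged_copy_scores_unity():
    rng = np.random.default_rng(0)
    arr = make_series(rng.uniform(300, 500, 30), "arrivals")
    # A leading query: its value this week equals arrivals 3 weeks later.
    lead = np.concatenate([arr.values[3:], rng.uniform(300, 500, 3)])
    q = make_series(lead, "q")
    table = dict((lag, r) for lag, r, _ in lagged_pearson(q, arr))
    assert table[3] == pytest.approx(1.0, abs=1e-12)

    neg = make_series(np.concatenate([-arr.values[2:], rng.uniform(0, 1, 2)]), "qneg")
    table = dict((lag, r) for lag, r, _ in lagged_pearson(neg, arr))
    assert table[2] == pytest.approx(-1.0, abs=1e-12)


def test_lagged_pearson_matches_covariance_definition():
    rng = np.random.default_rng(1)
    q = make_series(rng.normal(size=30), "q")
    arr = make_series(rng.normal(size=30), "a")
    for lag, r, p in lagged_pearson(q, arr, max_lag=7):
        x, y = q.values[: 30 - lag], arr.values[lag:]
        xc, yc = x - x.mean(), y - y.mean()
        r_def = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert abs(r - r_def) < 1e-12
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue, abs=1e-12)


def test_lagged_pearson_window_and_degenerate_behaviour():
    arr = make_series(np.arange(40.0), "a")
    const = make_series(np.full(40, 5.0), "c")
    res = lagged_pearson(const, arr, window=(0, 27))
    assert all(r == 0.0 and p == 1.0 for _, r, p in res)
    with pytest.raises(ValueError, match="window too short"):
        lagged_pearson(const, arr, window=(0, 9), max_lag=7)


# ---------------------------------------------------------------------------
# fdr_adjust


@pytest.mark.parametrize(
    "p_in, expected",
    [
        ([0.01], [0.01]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ],
)
def test_fdr_adjust_examples(p_in, expected):
    assert fdr_adjust(p_in) == pytest.approx(expected, abs=1e-12)


def test_fdr_adjust_matches_manual_step_up(rng):
    p = rng.uniform(size=37)
    order = np.argsort(p)
    m = len(p)
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    manual = np.empty(m)
    manual[order] = np.minimum(adj_sorted, 1.0)
    assert fdr_adjust(p) == pytest.approx(manual, abs=1e-12)


def test_fdr_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# select_queries


def test_select_queries_equals_bruteforce_double_loop(default_scenario):
    arrivals, _, panel = default_scenario
    small = QueryPanel(
        week_start=panel.week_start,
        queries=panel.queries.iloc[:, :18],
    )
    window, threshold, alpha = (0, 27), 0.30, 0.05
    got = select_queries(small, arrivals, window=window, threshold=threshold, alpha=alpha)

    # Brute force: query x lag Pearson by definition, best |r| with
    # smallest-lag ties, BH across best-lag p values.
    rows = []
    for name in small.names:
        best = None
        for lag in range(1, 8):
            x = small.queries[name].to_numpy()[: 27 - lag]
            y = arrivals.values[lag:27]
            r, p = stats.pearsonr(x, y)
            if best is None or abs(r) > abs(best[1]) + 1e-15:
                best = (lag, r, p)
        rows.append((name, *best))
    m = len(rows)
    ps = np.array([row[3] for row in rows])
    order = np.argsort(ps)
    adj = np.minimum.accumulate((ps[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    p_fdr = np.empty(m)
    p_fdr[order] = np.minimum(adj, 1.0)

    expected = {
        name: (lag, r, p, pf, abs(r) >= threshold and pf <= alpha)
        for (name, lag, r, p), pf in zip(rows, p_fdr)
    }
    assert len(got) == len(expected)
    for sel in got:
        lag, r, p, pf, selected = expected[sel.query]
        assert sel.best_lag == lag
        assert sel.r == pytest.approx(r, abs=1e-10)
        assert sel.p_raw == pytest.approx(p, abs=1e-10)
        assert sel.p_fdr == pytest.approx(pf, abs=1e-10)
        assert sel.selected == selected
    # Output ordering: by lag, then |r| descending.
    keys = [(s.best_lag, -abs(s.r)) for s in got]
    assert keys == sorted(keys)


def test_moderate_correlation_with_small_fdr_p_is_selected():
    """A query correlated ~0.3-0.5 at lag 2 on a long window clears both
    the |r| threshold and the FDR gate, like the weakest tabulated query."""
    rng = np.random.default_rng(4)
    n = 120
    arr_vals = rng.uniform(300, 500, n)
    arr = make_series(arr_vals, "arrivals")
    lead = np.empty(n)
    lead[: n - 2] = arr_vals[2:]
    lead[n - 2 :] = arr_vals[:2]
    signal = stats.zscore(lead) + rng.normal(scale=1.6, size=n)
    noise_cols = {f"n{i}": rng.uniform(0, 100, n) for i in range(10)}
    q = 100 * (signal - signal.min()) / np.ptp(signal)
    panel = _panel({"lead": q, **noise_cols})
    sels = {s.query: s for s in select_queries(panel, arr)}
    s = sels["lead"]
    assert s.selected and s.best_lag == 2
    assert 0.30 <= abs(s.r) <= 0.75
    assert s.p_fdr <= 0.05


def test_threshold_monotonicity(default_scenario):
    arrivals, _, panel = default_scenario
    small = QueryPanel(week_start=panel.week_start, queries=panel.queries.iloc[:, :40])
    loose = {s.query for s in select_queries(small, arrivals, window=(0, 27), threshold=0.30)
             if s.selected}
    tight = {s.query for s in select_queries(small, arrivals, window=(0, 27), threshold=0.45)
             if s.selected}
    assert tight <= loose


def test_empty_panel_returns_empty():
    grid = pd.DatetimeIndex(pd.date_range("2009-07-12", periods=40, freq="7D"))
    panel = QueryPanel(week_start=grid, queries=pd.DataFrame(index=grid))
    arr = make_series(np.random.default_rng(0).uniform(1, 2, 40))
    assert select_queries(panel, arr) == []


# ---------------------------------------------------------------------------
# build_index


def _selection(query, lag):
    return LagSelection(query=query, best_lag=lag, r=0.5, p_raw=0.01, p_fdr=0.02, selected=True)


def test_single_query_index_is_lagged_copy():
    vals = np.arange(10.0) * 3
    panel = _panel({"a": vals})
    idx = build_index(panel, [_selection("a", 1)])
    assert idx.start_week == 1
    assert np.array_equal(idx.series.values, vals[:-1])
    assert idx.provenance == [("a", 1)]


def test_two_query_index_matches_hand_shifted_table():
    a = np.arange(10.0)
    b = np.arange(10.0) ** 2
    panel = _panel({"a": a, "b": b / 2})
    idx = build_index(panel, [_selection("a", 1), _selection("b", 2)])
    # Hand-shifted: for t = 2..9, a[t-1] + b[t-2]/2.
    expected = [a[t - 1] + b[t - 2] / 2 for t in range(2, 10)]
    assert idx.series.values.tolist() == expected
    assert idx.series.week_start[0] == panel.week_start[2]


def test_zero_queries_give_zero_index_and_empty_selection_raises():
    panel = _panel({"a": np.zeros(8), "b": np.zeros(8)})
    idx = build_index(panel, [_selection("a", 1), _selection("b", 3)])
    assert np.array_equal(idx.series.values, np.zeros(5))
    with pytest.raises(EmptySelectionError):
        build_index(panel, [])


def test_index_linearity_in_the_panel(rng):
    n = 15
    A = {k: rng.uniform(0, 50, n) for k in "abc"}
    B = {k: rng.uniform(0, 50, n) for k in "abc"}
    sels = [_selection("a", 1), _selection("b", 4), _selection("c", 2)]
    idx_a = build_index(_panel(A), sels).series.values
    idx_b = build_index(_panel(B), sels).series.values
    idx_ab = build_index(_panel({k: A[k] + B[k] for k in A}), sels).series.values
    assert np.allclose(idx_ab, idx_a + idx_b, atol=1e-12)


def test_normalize_panel_uses_fit_window_and_preserves_truth(default_scenario):
    _, _, panel = default_scenario
    normed = normalize_panel(panel, fit_window=(0, 27))
    sub = normed.queries.iloc[:27]
    assert sub.min().min() >= 0.0 and sub.max().max() <= 100.0
    assert np.isclose(sub.max(axis=0), 100.0).all()
    assert normed.truth == panel.truth
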