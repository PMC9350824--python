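"""Feature assembly, normalization, temporal split and model contracts."""

import numpy as np
import pandas as pd
import pytest

from edcast.forecasting import (
    DegenerateWindowError,
    FeatureMatrix,
    ModelSpec,
    build_features,
    min_max_normalize,
    run_forecast,
    temporal_split,
)
from edcast.pipeline import build_search_index
from edcast.synthetic import SyntheticConfig, generate_scenario


@pytest.fixture(scope="module")
def scenario():
    return generate_scenario(SyntheticConfig(seed=2))


@pytest.fixture(scope="module")
def scenario_with_index(scenario):
    arrivals, covariates, panel = scenario
    _, idx = build_search_index(panel, arrivals)
    assert idx is not None
    return arrivals, covariates, panel, idx


# ---------------------------------------------------------------------------
# min-max normalization


def test_min_max_affine_map_and_round_trip(rng):
    normed, params = min_max_normalize(np.array([2.0, 4.0, 6.0]), slice(None))
    assert normed.tolist() == [0.0, 0.5, 1.0]
    x = rng.normal(size=50)
    normed, params = min_max_normalize(x, slice(None))
    assert np.abs(params.inverse(normed) - x).max() < 1e-12


def test_min_max_extrapolates_beyond_fit_window():
    v = np.array([0.0, 10.0, 15.0])
    normed, _ = min_max_normalize(v, slice(0, 2))
    assert normed.tolist() == [0.0, 1.0, 1.5]
    with pytest.raises(DegenerateWindowError):
        min_max_normalize(np.array([3.0, 3.0, 4.0]), slice(0, 2))


# ---------------------------------------------------------------------------
# build_features


def test_row_count_without_index(scenario):
    arrivals, covariates, _ = scenario
    f = build_features(arrivals, covariates, predictor_set="arrivals")
    assert len(f) == len(arrivals) - 1  # one row lost to the one-step lag
    assert list(f.X.columns) == ["arrivals_prev"]


def test_feature_rows_match_independent_builder(scenario_with_index):
    """Leakage audit: rebuild every row from raw inputs using only the
    permitted weeks and compare exactly."""
    arrivals, covariates, _, idx = scenario_with_index
    f = build_features(arrivals, covariates, index=idx, predictor_set="index")
    for row_i, s in enumerate(f.target_positions):
        row = f.X.iloc[row_i]
        assert row["arrivals_prev"] == arrivals.values[s - 1]
        assert row[f"month_{covariates.month[s]:02d}"] == 1.0
        assert row.filter(like="month_").sum() == 1.0
        assert row["temp_high_prev"] == covariates.temp_high[s - 1]
        assert row["temp_low_prev"] == covariates.temp_low[s - 1]
        assert row["public_holidays"] == covariates.public_holidays[s]
        assert row["school_holidays"] == covariates.school_holidays[s]
        assert row["search_index"] == idx.series.values[s - idx.start_week]
        assert f.y[row_i] == arrivals.values[s]


def test_predictor_sets_are_nested(scenario_with_index):
    arrivals, covariates, _, idx = scenario_with_index
    cols = {}
    for pset in ("arrivals", "traditional", "index"):
        f = build_features(arrivals, covariates, index=idx, predictor_set=pset)
        cols[pset] = set(f.X.columns)
    assert cols["arrivals"] < cols["traditional"] < cols["index"]


def test_alignment_trims_startup_weeks_for_all_sets(scenario_with_index):
    arrivals, covariates, _, idx = scenario_with_index
    f_plain = build_features(arrivals, covariates, predictor_set="arrivals")
    f_trim = build_features(arrivals, covariates, index=idx, predictor_set="arrivals")
    assert f_trim.target_positions[0] == max(1, idx.start_week)
    assert len(f_trim) <= len(f_plain)


def test_panel_column_permutation_leaves_features_unchanged(scenario):
    from edcast.weekly import QueryPanel

    arrivals, covariates, panel = scenario
    rng = np.random.default_rng(0)
    perm = rng.permutation(panel.queries.shape[1])
    shuffled = QueryPanel(
        week_start=panel.week_start,
        queries=panel.queries.iloc[:, perm],
        truth=panel.truth,
    )
    _, idx1 = build_search_index(panel, arrivals)
    _, idx2 = build_search_index(shuffled, arrivals)
    f1 = build_features(arrivals, covariates, index=idx1, predictor_set="index")
    f2 = build_features(arrivals, covariates, index=idx2, predictor_set="index")
    assert np.allclose(f1.X.to_numpy(), f2.X.to_numpy(), atol=1e-9)


def test_index_set_requires_index(scenario):
    arrivals, covariates, _ = scenario
    with pytest.raises(ValueError, match="requires a search index"):
        build_features(arrivals, covariates, predictor_set="index")


# ---------------------------------------------------------------------------
# temporal_split


def test_split_is_a_contiguous_partition(scenario):
    arrivals, covariates, _ = scenario
    f = build_features(arrivals, covariates, predictor_set="arrivals")
    split = temporal_split(f, train_weeks=27)
    assert len(split.test_idx) == 24  # 51 weeks -> 24 test targets
    all_idx = np.concatenate([split.train_idx, split.test_idx])
    assert np.array_equal(np.sort(all_idx), np.arange(len(f)))
    assert split.train_idx.max() < split.test_idx.min()

    split2 = temporal_split(f, train_weeks=28)
    assert len(split2.train_idx) == len(split.train_idx) + 1
    with pytest.raises(ValueError):
        temporal_split(f, train_weeks=len(arrivals))


# ---------------------------------------------------------------------------
# run_forecast


def _linear_feature_matrix(n=40, seed=0):
    rng = np.random.default_rng(seed)
    grid = pd.DatetimeIndex(pd.date_range("2009-07-12", periods=n, freq="7D"))
    X = pd.DataFrame(
        {f"x{j}": rng.uniform(0, 1, n) for j in range(4)}, index=grid
    )
    return X, grid, rng


def test_glm_recovers_exact_linear_rule():
    X, grid, rng = _linear_feature_matrix()
    y = 300 + 40 * X["x0"].to_numpy() - 25 * X["x2"].to_numpy()
    f = FeatureMatrix(
        X=X, y=y, target_weeks=grid, target_positions=np.arange(1, len(y) + 1),
        predictor_set="traditional",
    )
    split = temporal_split(f, train_weeks=28)
    res = run_forecast(f, split, "glm")
    assert res.metrics("test").mape < 1e-8


def test_glm_coefficients_match_normal_equations():
    X, grid, rng = _linear_feature_matrix(n=30, seed=5)
    y = rng.uniform(200, 400, 30)
    f = FeatureMatrix(
        X=X, y=y, target_weeks=grid, target_positions=np.arange(1, 31),
        predictor_set="traditional",
    )
    split = temporal_split(f, train_weeks=23)
    res = run_forecast(f, split, "glm")

    # Independent oracle: replicate the normalization, solve the normal
    # equations, de-normalize.
    def norm(v, idx):
        lo, hi = v[idx].min(), v[idx].max()
        return (v - lo) / (hi - lo), lo, hi

    cols = [norm(X[c].to_numpy(), split.train_idx)[0] for c in X.columns]
    yn, ylo, yhi = norm(y, split.train_idx)
    A = np.column_stack([np.ones(len(y)), *cols])
    At = A[split.train_idx]
    coef = np.linalg.solve(At.T @ At, At.T @ yn[split.train_idx])
    pred = (A @ coef) * (yhi - ylo) + ylo
    assert np.abs(res.predicted_test - pred[split.test_idx]).max() < 1e-8


def test_elm_forecast_is_reproducible(scenario_with_index):
    arrivals, covariates, _, idx = scenario_with_index
    f = build_features(arrivals, covariates, index=idx, predictor_set="index")
    split = temporal_split(f)
    r1 = run_forecast(f, split, ModelSpec("elm", seed=5))
    r2 = run_forecast(f, split, ModelSpec("elm", seed=5))
    assert np.array_equal(r1.predicted_test, r2.predicted_test)
    assert r1.metadata["hidden_nodes"] == 150


def test_unknown_model_rejected(scenario):
    arrivals, covariates, _ = scenario
    f = build_features(arrivals, covariates, predictor_set="arrivals")
    split = temporal_split(f)
    with pytest.raises(ValueError, match="unknown model"):
        run_forecast(f, split, "prophet")


@pytest.mark.parametrize("model", ["svm", "rf", "ann", "arima", "arimax"])
def test_adapter_models_produce_finite_forecasts(scenario_with_index, model):
    arrivals, covariates, _, idx = scenario_with_index
    f = build_features(arrivals, covariates, index=idx, predictor_set="traditional")
    split = temporal_split(f)
    res = run_forecast(f, split, ModelSpec(model, seed=1))
    assert np.isfinite(res.predicted_test).all()
    assert len(res.predicted_test) == len(split.test_idx)
    assert res.metrics("test").mape < 50.0  # sane on a well-behaved scenario
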