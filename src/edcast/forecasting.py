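"""One-week-ahead feature assembly, train/test split and the model registry.

For a target week t+1 the permitted information set is: arrivals of week
t, the month of week t+1 (one-hot), the temperatures of week t, the
public- and school-holiday counts of week t+1 (known in advance from the
calendar), and -- in the richest predictor set -- the search index at week
t+1, which by construction only aggregates query values from weeks t-6..t.
Three nested predictor sets are supported:

* ``arrivals``      -- last week's arrivals only;
* ``traditional``   -- plus calendar / weather / holiday covariates;
* ``index``         -- plus the internet search index.

The split is a contiguous prefix/suffix cut at a fixed week (default: the
first 27 weeks train, the rest test); every column is min-max normalized
with training-window statistics only, and predictions are mapped back to
the original arrivals scale before any metric is computed.

Natively implemented models: the extreme learning machine (module
:mod:`edcast.elm`) and a Gaussian GLM fitted by ordinary least squares.
ARIMA(X) (statsmodels) and SVM / ANN / RF (scikit-learn) adapters delegate
to established estimators behind the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import elm as elm_mod
from .evaluation import MetricReport, compute_metrics
from .index import SearchIndex
from .weekly import TraditionalCovariates, WeeklySeries

PREDICTOR_SETS = ("arrivals", "traditional", "index")
_SET_ALIASES = {
    "arrivals": "arrivals",
    "arrivals_only": "arrivals",
    "traditional": "traditional",
    "arrivals_traditional": "traditional",
    "index": "index",
    "arrivals_traditional_index": "index",
}

# Hidden-node counts pinned per predictor set for the ELM.
ELM_HIDDEN_NODES = {"arrivals": 20, "traditional": 120, "index": 150}


class DegenerateWindowError(ValueError):
    """The normalization fit window is constant."""


@dataclass(frozen=True)
class MinMaxParams:
    lo: float
    hi: float

    def transform(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) * (self.hi - self.lo) + self.lo


def min_max_normalize(
    values: np.ndarray, fit_window: slice | np.ndarray
) -> tuple[np.ndarray, MinMaxParams]:
    """Scale by training-window min/max; out-of-window values may leave [0, 1]."""
    v = np.asarray(values, dtype=float)
    ref = v[fit_window]
    if ref.size == 0:
        raise ValueError("fit_window must be nonempty")
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        raise DegenerateWindowError("fit window is constant; min-max scaling undefined")
    params = MinMaxParams(lo, hi)
    return params.transform(v), params


@dataclass
class FeatureMatrix:
    """Per-target-week predictors and targets on the original scale."""

    X: pd.DataFrame  # one row per target week
    y: np.ndarray  # arrivals at the target week
    target_weeks: pd.DatetimeIndex
    target_positions: np.ndarray  # positions of the target weeks on the scenario grid
    predictor_set: str
    binary_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


def build_features(
    arrivals: WeeklySeries,
    covariates: TraditionalCovariates,
    index: Optional[SearchIndex] = None,
    predictor_set: str = "index",
    align_to_index: bool = True,
) -> FeatureMatrix:
    """Assemble the one-week-ahead design matrix for one predictor set.

    When an ``index`` is supplied and ``align_to_index`` is true, the
    start-up weeks where the index is undefined are dropped from *every*
    predictor set so that accuracy comparisons across sets share identical
    target weeks.
    """
    pset = _SET_ALIASES.get(predictor_set)
    if pset is None:
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    if pset == "index" and index is None:
        raise ValueError("predictor set 'index' requires a search index")
    n = len(arrivals)
    if len(covariates) != n or not (covariates.week_start == arrivals.week_start).all():
        raise ValueError("arrivals and covariates must share the week grid")

    first = 1
    if index is not None and align_to_index:
        first = max(first, index.start_week)
    positions = np.arange(first, n)  # target week positions t+1

    cols: dict[str, np.ndarray] = {"arrivals_prev": arrivals.values[positions - 1]}
    binary: list[str] = []
    if pset in ("traditional", "index"):
        month = covariates.month[positions]
        for m in range(1, 13):
            cname = f"month_{m:02d}"
            cols[cname] = (month == m).astype(float)
            binary.append(cname)
        cols["temp_high_prev"] = covariates.temp_high[positions - 1]
        cols["temp_low_prev"] = covariates.temp_low[positions - 1]
        cols["public_holidays"] = covariates.public_holidays[positions].astype(float)
        cols["school_holidays"] = covariates.school_holidays[positions].astype(float)
    if pset == "index":
        offset = positions - index.start_week
        if offset.min() < 0 or offset.max() >= len(index.series):
            raise ValueError("index does not cover every target week")
        cols["search_index"] = index.series.values[offset]

    X = pd.DataFrame(cols, index=arrivals.week_start[positions])
    return FeatureMatrix(
        X=X,
        y=arrivals.values[positions],
        target_weeks=arrivals.week_start[positions],
        target_positions=positions,
        predictor_set=pset,
        binary_columns=binary,
    )


@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_weeks: int


def temporal_split(features: FeatureMatrix, train_weeks: int = 27) -> Split:
    """Contiguous prefix/suffix split at scenario week ``train_weeks``.

    Rows whose target week falls within the first ``train_weeks`` weeks of
    the scenario grid form the training set; the remainder is the test
    set.  No shuffling ever happens.
    """
    pos = features.target_positions
    train_mask = pos < train_weeks
    if train_mask.sum() == 0 or train_mask.all():
        raise ValueError("train_weeks leaves an empty train or test split")
    return Split(
        train_idx=np.flatnonzero(train_mask),
        test_idx=np.flatnonzero(~train_mask),
        train_weeks=train_weeks,
    )


@dataclass
class ModelSpec:
    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class ForecastResult:
    model: str
    predictor_set: str
    train_weeks_index: pd.DatetimeIndex
    test_weeks_index: pd.DatetimeIndex
    actual_train: np.ndarray
    predicted_train: np.ndarray
    actual_test: np.ndarray
    predicted_test: np.ndarray
    metadata: dict = field(default_factory=dict)

    def metrics(self, which: str = "test", mismatch_threshold: float = 0.18) -> MetricReport:
        if which == "test":
            return compute_metrics(self.actual_test, self.predicted_test, mismatch_threshold)
        return compute_metrics(self.actual_train, self.predicted_train, mismatch_threshold)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "predictor_set": self.predictor_set,
            "train": [
                {"week_start": w.strftime("%Y-%m-%d"), "actual": float(a), "predicted": float(p)}
                for w, a, p in zip(
                    self.train_weeks_index, self.actual_train, self.predicted_train
                )
            ],
            "test": [
                {"week_start": w.strftime("%Y-%m-%d"), "actual": float(a), "predicted": float(p)}
                for w, a, p in zip(self.test_weeks_index, self.actual_test, self.predicted_test)
            ],
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# Normalization of a feature matrix


def _normalize_design(
    features: FeatureMatrix, split: Split
) -> tuple[np.ndarray, np.ndarray, MinMaxParams, dict]:
    """Min-max normalize continuous columns and the target on train rows.

    One-hot indicator columns pass through untouched; continuous columns
    constant on the training window are mapped to 0 (they carry no
    training information, and scaling them is undefined).
    """
    X = features.X.copy()
    col_params: dict[str, Optional[MinMaxParams]] = {}
    fit = split.train_idx
    for col in X.columns:
        if col in features.binary_columns:
            col_params[col] = None
            continue
        v = X[col].to_numpy(dtype=float)
        try:
            normed, params = min_max_normalize(v, fit)
        except DegenerateWindowError:
            normed, params = np.zeros_like(v), None
        X[col] = normed
        col_params[col] = params
    y_normed, y_params = min_max_normalize(features.y, fit)
    return X.to_numpy(dtype=float), y_normed, y_params, col_params


# ---------------------------------------------------------------------------
# Model adapters (uniform contract: fit on train, predict train+test)


def _fit_glm(Xtr, ytr, Xte, spec, feature_names, binary_cols):
    """Gaussian GLM == ordinary least squares, fitted natively.

    One month indicator is dropped (with an intercept present the full
    one-hot is singular); training-constant columns are removed.  Any
    remaining rank deficiency is an estimation error.
    """
    drop = set()
    for i in range(Xtr.shape[1]):
        if np.ptp(Xtr[:, i]) == 0:
            drop.add(i)
    # The month indicators present in training sum to the intercept; drop one.
    month_cols = [
        i for i, c in enumerate(feature_names) if c.startswith("month_") and i not in drop
    ]
    if month_cols:
        drop.add(month_cols[0])
    keep = [i for i in range(Xtr.shape[1]) if i not in drop]
    A = np.column_stack([np.ones(len(Xtr)), Xtr[:, keep]])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix for the GLM")
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    B = np.column_stack([np.ones(len(Xte)), Xte[:, keep]])
    return A @ coef, B @ coef, {"n_coefficients": len(coef)}


def _fit_elm(Xtr, ytr, Xte, spec, feature_names, binary_cols, predictor_set):
    L = spec.params.get("hidden_nodes", ELM_HIDDEN_NODES[predictor_set])
    activation = spec.params.get("activation", "satlins")
    n_restarts = spec.params.get("n_restarts", 5)
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(n_restarts) % (2**31)
    train = elm_mod.SampleSet(Xtr, ytr)
    preds_tr, preds_te = [], []
    for s in child_seeds:
        model = elm_mod.elm_fit(train, L=L, activation=activation, seed=int(s))
        preds_tr.append(elm_mod.elm_predict(model, Xtr).ravel())
        preds_te.append(elm_mod.elm_predict(model, Xte).ravel())
    meta = {"hidden_nodes": L, "activation": activation, "n_restarts": n_restarts}
    return np.mean(preds_tr, axis=0), np.mean(preds_te, axis=0), meta


def _fit_sklearn(Xtr, ytr, Xte, spec, feature_names, binary_cols):
    name = spec.name
    if name == "svm":
        from sklearn.svm import SVR

        est = SVR(kernel="rbf", **spec.params)
    elif name == "rf":
        from sklearn.ensemble import RandomForestRegressor

        est = RandomForestRegressor(
            n_estimators=spec.params.get("n_estimators", 300),
            random_state=spec.seed,
            **{k: v for k, v in spec.params.items() if k != "n_estimators"},
        )
    elif name == "ann":
        from sklearn.neural_network import MLPRegressor

        est = MLPRegressor(
            hidden_layer_sizes=spec.params.get("hidden_layer_sizes", (8,)),
            activation="logistic",
            max_iter=spec.params.get("max_iter", 3000),
            random_state=spec.seed,
        )
    else:  # pragma: no cover
        raise ValueError(name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xtr, ytr)
    return est.predict(Xtr), est.predict(Xte), {"estimator": type(est).__name__}


def _fit_arima(features: FeatureMatrix, split: Split, spec: ModelSpec, with_exog: bool):
    """ARIMA(X) via statsmodels SARIMAX with a small AIC order search.

    The model is fitted on the training window only; test predictions are
    one-step-ahead with fixed parameters (the fitted model is applied to
    the full series, so each forecast conditions on actual history).
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    y = features.y.astype(float)
    ytr = y[split.train_idx]
    exog = None
    if with_exog:
        keep = [c for c in features.X.columns if c != "arrivals_prev"]
        exog = features.X[keep].to_numpy(dtype=float)
    exog_tr = exog[split.train_idx] if exog is not None else None

    orders = spec.params.get("orders")
    if orders is None:
        orders = [(p, d, q) for p in (0, 1, 2) for d in (0, 1) for q in (0, 1)]
        orders = [o for o in orders if sum(o) > 0]
    best = None
    for order in orders:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = SARIMAX(
                    ytr, exog=exog_tr, order=order, trend="c" if order[1] == 0 else None
                ).fit(disp=False)
            if best is None or res.aic < best[1]:
                best = (order, res.aic, res)
        except Exception:
            continue
    if best is None:
        raise RuntimeError("no ARIMA order could be estimated")
    order, _, res = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = res.apply(y, exog=exog)
        pred = full.get_prediction().predicted_mean
    return pred[split.train_idx], pred[split.test_idx], {"order": list(order)}


AVAILABLE_MODELS = ("elm", "glm", "arima", "arimax", "svm", "ann", "rf")


def run_forecast(
    features: FeatureMatrix, split: Split, model_spec: ModelSpec | str
) -> ForecastResult:
    """Fit one model on the training rows and forecast both splits.

    Feature-driven models see the min-max normalized design (training
    statistics only) and their predictions are de-normalized back to the
    original arrivals scale.  ARIMA(X) works on the raw arrivals series
    directly.
    """
    spec = ModelSpec(model_spec) if isinstance(model_spec, str) else model_spec
    if spec.name not in AVAILABLE_MODELS:
        raise ValueError(f"unknown model {spec.name!r}; available: {AVAILABLE_MODELS}")

    if spec.name in ("arima", "arimax"):
        pred_tr, pred_te, meta = _fit_arima(features, split, spec, spec.name == "arimax")
    else:
        Xn, yn, y_params, _ = _normalize_design(features, split)
        Xtr, Xte = Xn[split.train_idx], Xn[split.test_idx]
        ytr = yn[split.train_idx]
        names = list(features.X.columns)
        if spec.name == "glm":
            ptr, pte, meta = _fit_glm(Xtr, ytr, Xte, spec, names, features.binary_columns)
        elif spec.name == "elm":
            ptr, pte, meta = _fit_elm(
                Xtr, ytr, Xte, spec, names, features.binary_columns, features.predictor_set
            )
        else:
            ptr, pte, meta = _fit_sklearn(Xtr, ytr, Xte, spec, names, features.binary_columns)
        pred_tr, pred_te = y_params.inverse(ptr), y_params.inverse(pte)

    return ForecastResult(
        model=spec.name,
        predictor_set=features.predictor_set,
        train_weeks_index=features.target_weeks[split.train_idx],
        test_weeks_index=features.target_weeks[split.test_idx],
        actual_train=features.y[split.train_idx],
        predicted_train=np.asarray(pred_tr, dtype=float),
        actual_test=features.y[split.test_idx],
        predicted_test=np.asarray(pred_te, dtype=float),
        metadata={**meta, "seed": spec.seed},
    )
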