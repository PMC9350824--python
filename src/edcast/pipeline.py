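"""End-to-end orchestration: scenario -> index -> validation -> forecasts.

One call runs the full analysis on a (synthetic or loaded) scenario:

1. screen the query panel on the training window and fuse the selected
   queries into the internet search index;
2. validate the index/arrivals relationship on the training window
   (Pearson, ADF, Johansen, Granger);
3. assemble the three nested predictor sets, split train/test at a fixed
   week, run the requested models, and collect MAPE/RMSE/mismatch-week
   metrics plus pairwise Diebold-Mariano comparisons.

If screening selects no query the index predictor set is skipped and the
run is flagged; everything else proceeds.  All randomness is controlled
by the scenario config seed and a single model seed, and the emitted
report dictionary is a pure function of those seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .evaluation import dm_test, pairwise_dm_table
from .forecasting import ModelSpec, build_features, run_forecast, temporal_split
from .index import (
    EmptySelectionError,
    LagSelection,
    SearchIndex,
    build_index,
    normalize_panel,
    select_queries,
)
from .synthetic import SyntheticConfig, generate_scenario
from .validation import RelationshipReport, validate
from .weekly import QueryPanel, TraditionalCovariates, WeeklySeries


@dataclass
class PipelineResult:
    arrivals: WeeklySeries
    covariates: TraditionalCovariates
    panel: QueryPanel
    selections: list[LagSelection]
    search_index: Optional[SearchIndex]
    validation: Optional[RelationshipReport]
    forecasts: dict  # (model, predictor_set) -> ForecastResult
    flags: list[str] = field(default_factory=list)

    def metrics_table(self) -> dict:
        """Model x predictor-set x split accuracy, mirroring a results table."""
        out: dict = {}
        for (model, pset), res in self.forecasts.items():
            entry = out.setdefault(pset, {}).setdefault(model, {})
            for which in ("train", "test"):
                m = res.metrics(which)
                entry[which] = {
                    "mape": m.mape,
                    "rmse": m.rmse,
                    "n": m.n,
                    "mismatch_weeks": m.mismatch_weeks,
                }
        return out

    def to_report(self) -> dict:
        """JSON-serializable end-to-end report (deterministic given seeds)."""
        report = {
            "n_weeks": len(self.arrivals),
            "selections": [s.to_dict() for s in self.selections if s.selected],
            "n_selected": sum(s.selected for s in self.selections),
            "index_provenance": self.search_index.provenance if self.search_index else None,
            "validation": self.validation.to_dict() if self.validation else None,
            "metrics": self.metrics_table(),
            "flags": self.flags,
        }
        return _round_floats(report)


def _round_floats(obj, digits: int = 10):
    """Round floats for byte-stable JSON across runs."""
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), digits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), digits)
    return obj


def build_search_index(
    panel: QueryPanel,
    arrivals: WeeklySeries,
    train_weeks: int = 27,
    threshold: float = 0.30,
    alpha: float = 0.05,
    max_lag: int = 7,
) -> tuple[list[LagSelection], Optional[SearchIndex]]:
    """Screen on the training window and fuse; None when nothing selected.

    Queries are min-max weighted on the training window before summation
    so no single 0-100 query dominates the fused index.
    """
    selections = select_queries(
        panel, arrivals, window=(0, train_weeks), max_lag=max_lag, threshold=threshold, alpha=alpha
    )
    try:
        weighted = normalize_panel(panel, fit_window=(0, train_weeks))
        search_index = build_index(weighted, selections)
    except EmptySelectionError:
        search_index = None
    return selections, search_index


def run_pipeline(
    config: Optional[SyntheticConfig] = None,
    scenario: Optional[tuple] = None,
    train_weeks: int = 27,
    models: Sequence[str] = ("elm", "glm"),
    predictor_sets: Sequence[str] = ("arrivals", "traditional", "index"),
    threshold: float = 0.30,
    alpha: float = 0.05,
    model_seed: int = 0,
    run_validation: bool = True,
    align_to_index: bool = True,
) -> PipelineResult:
    """Run the full analysis; pass either a config or a prebuilt scenario."""
    if scenario is None:
        scenario = generate_scenario(config or SyntheticConfig())
    arrivals, covariates, panel = scenario

    selections, search_index = build_search_index(
        panel, arrivals, train_weeks=train_weeks, threshold=threshold, alpha=alpha
    )
    flags: list[str] = []
    sets = list(predictor_sets)
    if search_index is None:
        flags.append("no query selected; index predictor set skipped")
        sets = [s for s in sets if s != "index"]

    validation_report = None
    if run_validation and search_index is not None:
        start = search_index.start_week
        arr_tr = arrivals.slice(start, train_weeks)
        idx_tr = search_index.series.slice(0, train_weeks - start)
        try:
            n_tr = len(arr_tr)
            validation_report = validate(arr_tr, idx_tr, max_lag=max(1, min(4, n_tr // 5)))
        except (ValueError, np.linalg.LinAlgError) as exc:
            flags.append(f"validation degenerate: {exc}")

    forecasts = {}
    for pset in sets:
        features = build_features(
            arrivals,
            covariates,
            index=search_index if (pset == "index" or align_to_index) else None,
            predictor_set=pset,
            align_to_index=align_to_index,
        )
        split = temporal_split(features, train_weeks=train_weeks)
        for model in models:
            spec = ModelSpec(model, seed=model_seed)
            forecasts[(model, pset)] = run_forecast(features, split, spec)

    return PipelineResult(
        arrivals=arrivals,
        covariates=covariates,
        panel=panel,
        selections=selections,
        search_index=search_index,
        validation=validation_report,
        forecasts=forecasts,
        flags=flags,
    )


def dm_comparisons(result: PipelineResult, h: int = 1) -> dict:
    """Pairwise DM tables per predictor set plus with/without-index pairs."""
    out: dict = {"per_set": {}, "with_vs_without_index": {}}
    by_set: dict[str, dict[str, np.ndarray]] = {}
    actuals: dict[str, np.ndarray] = {}
    for (model, pset), res in result.forecasts.items():
        by_set.setdefault(pset, {})[model] = res.predicted_test
        actuals[pset] = res.actual_test
    for pset, preds in by_set.items():
        if len(preds) >= 2:
            table = pairwise_dm_table(actuals[pset], preds, h=h)
            out["per_set"][pset] = {
                f"{ref}|{te}": r.to_dict() for (ref, te), r in table.items()
            }
    if "index" in by_set and "traditional" in by_set:
        for model, pred in by_set["index"].items():
            ref = by_set["traditional"].get(model)
            if ref is not None and len(ref) == len(pred):
                r = dm_test(actuals["index"], ref, pred, h=h)
                out["with_vs_without_index"][model] = r.to_dict()
    return out


def truncate_scenario(
    scenario: tuple[WeeklySeries, TraditionalCovariates, QueryPanel], length: int
) -> tuple[WeeklySeries, TraditionalCovariates, QueryPanel]:
    """First ``length`` weeks of a scenario bundle."""
    arrivals, cov, panel = scenario
    if not (1 <= length <= len(arrivals)):
        raise ValueError("length must lie within the scenario")
    cov_t = TraditionalCovariates(
        week_start=cov.week_start[:length],
        month=cov.month[:length],
        temp_high=cov.temp_high[:length],
        temp_low=cov.temp_low[:length],
        public_holidays=cov.public_holidays[:length],
        school_holidays=cov.school_holidays[:length],
    )
    panel_t = QueryPanel(
        week_start=panel.week_start[:length],
        queries=panel.queries.iloc[:length],
        truth=panel.truth,
    )
    return arrivals.slice(0, length), cov_t, panel_t


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
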