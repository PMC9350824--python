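"""Weekly time-series containers shared by every stage of the pipeline.

The analysis operates on a contiguous weekly grid: each week opens on a
Sunday and closes the following Saturday, and the value attached to a week
is the average daily ED arrival count (or a query's search popularity) for
that week.  Three small containers carry the data between stages:

* :class:`WeeklySeries` -- one value per week (arrivals, one query, the
  fused search index).
* :class:`TraditionalCovariates` -- the calendar / weather / holiday
  exogenous variables aligned to the same grid.
* :class:`QueryPanel` -- a week x query matrix of search-popularity values
  in [0, 100], optionally annotated with the ground-truth plantings of a
  synthetic scenario.

Gaps in the week grid are construction-time errors, never a runtime state:
every constructor validates contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

WEEK = pd.Timedelta(days=7)


def _check_week_grid(week_start: pd.DatetimeIndex, context: str) -> pd.DatetimeIndex:
    week_start = pd.DatetimeIndex(week_start)
    if len(week_start) < 1:
        raise ValueError(f"{context}: at least one week is required")
    if len(week_start) > 1:
        deltas = np.diff(week_start.values)
        if not (deltas == np.timedelta64(7, "D")).all():
            raise ValueError(
                f"{context}: week_start must advance by exactly 7 days per step"
            )
    return week_start


@dataclass
class WeeklySeries:
    """A contiguous weekly-indexed numeric series.

    Parameters
    ----------
    week_start
        Dates of the Sunday opening each week, strictly 7 days apart.
    values
        One finite value per week.
    name
        Label used in tables and CSV headers.
    """

    week_start: pd.DatetimeIndex
    values: np.ndarray
    name: str = "series"

    def __post_init__(self) -> None:
        self.week_start = _check_week_grid(self.week_start, f"WeeklySeries({self.name!r})")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.week_start):
            raise ValueError(
                f"WeeklySeries({self.name!r}): values must be 1-D and match the week grid"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"WeeklySeries({self.name!r}): missing/non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.week_start, name=self.name)

    @classmethod
    def from_pandas(cls, s: pd.Series, name: Optional[str] = None) -> "WeeklySeries":
        return cls(pd.DatetimeIndex(s.index), s.to_numpy(dtype=float), name or str(s.name))

    def slice(self, start: int, stop: int) -> "WeeklySeries":
        """Positional sub-series [start, stop); the grid stays contiguous."""
        return WeeklySeries(self.week_start[start:stop], self.values[start:stop], self.name)

    def same_grid(self, other: "WeeklySeries") -> bool:
        return len(self) == len(other) and (self.week_start == other.week_start).all()


@dataclass
class TraditionalCovariates:
    """Calendar, weather and holiday covariates on the arrivals week grid.

    ``month`` is the calendar month (1-12) of each week's Sunday;
    ``temp_high`` / ``temp_low`` are weekly mean daily extreme temperatures
    in degrees Celsius; the two holiday fields count days (0-7) within the
    week.
    """

    week_start: pd.DatetimeIndex
    month: np.ndarray
    temp_high: np.ndarray
    temp_low: np.ndarray
    public_holidays: np.ndarray
    school_holidays: np.ndarray

    def __post_init__(self) -> None:
        self.week_start = _check_week_grid(self.week_start, "TraditionalCovariates")
        n = len(self.week_start)
        self.month = np.asarray(self.month, dtype=int)
        self.temp_high = np.asarray(self.temp_high, dtype=float)
        self.temp_low = np.asarray(self.temp_low, dtype=float)
        self.public_holidays = np.asarray(self.public_holidays, dtype=int)
        self.school_holidays = np.asarray(self.school_holidays, dtype=int)
        for label, arr in [
            ("month", self.month),
            ("temp_high", self.temp_high),
            ("temp_low", self.temp_low),
            ("public_holidays", self.public_holidays),
            ("school_holidays", self.school_holidays),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"TraditionalCovariates: {label} must have length {n}")
        if not ((self.month >= 1) & (self.month <= 12)).all():
            raise ValueError("TraditionalCovariates: month must lie in 1..12")
        for label, arr in [
            ("public_holidays", self.public_holidays),
            ("school_holidays", self.school_holidays),
        ]:
            if not ((arr >= 0) & (arr <= 7)).all():
                raise ValueError(f"TraditionalCovariates: {label} must lie in 0..7")
        if not (self.temp_low <= self.temp_high).all():
            raise ValueError("TraditionalCovariates: temp_low must not exceed temp_high")

    def __len__(self) -> int:
        return len(self.week_start)

    def to_pandas(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.month,
                "temp_high": self.temp_high,
                "temp_low": self.temp_low,
                "public_holidays": self.public_holidays,
                "school_holidays": self.school_holidays,
            },
            index=self.week_start,
        )


@dataclass
class Planting:
    """Ground truth for one synthetic query: its lead lag and signed effect."""

    query: str
    lag: int
    effect: float  # signed; |effect| is the target population |r|

    def __post_init__(self) -> None:
        if not (1 <= int(self.lag) <= 7):
            raise ValueError("Planting: lag must lie in 1..7")


@dataclass
class QueryPanel:
    """Week x query matrix of search-popularity values in [0, 100]."""

    week_start: pd.DatetimeIndex
    queries: pd.DataFrame
    truth: Optional[list[Planting]] = field(default=None)

    def __post_init__(self) -> None:
        self.week_start = _check_week_grid(self.week_start, "QueryPanel")
        if len(self.queries) != len(self.week_start):
            raise ValueError("QueryPanel: queries must share the week grid")
        vals = self.queries.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 100):
            raise ValueError("QueryPanel: query values must be finite and within [0, 100]")
        self.queries = self.queries.set_axis(self.week_start, axis=0)
        if self.truth is not None:
            names = set(self.queries.columns)
            for p in self.truth:
                if p.query not in names:
                    raise ValueError(f"QueryPanel: truth query {p.query!r} not in panel")

    def __len__(self) -> int:
        return len(self.week_start)

    @property
    def names(self) -> list[str]:
        return list(self.queries.columns)

    def column(self, name: str) -> WeeklySeries:
        return WeeklySeries(self.week_start, self.queries[name].to_numpy(), name)
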