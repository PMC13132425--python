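"""Domain types and I/O for daily emergency-department arrival series.

The canonical layout is one row per calendar day with the arrival count
``y`` and 17 exogenous features ``X1``–``X17``: eight calendar codes
(year, semester, month, day-of-week, recoded day-of-week, holiday,
after-holiday, calendar-event class) and nine meteorological reals
(max/min/mean temperature, temperature range, max/mean wind speed, mean
rain, mean relative humidity, sunny hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_KEYS",
    "CALENDAR_KEYS",
    "METEO_KEYS",
    "FEATURE_LABELS",
    "SchemaError",
    "ValidationError",
    "SplitSpec",
    "TimeSeriesDataset",
    "read_dataset",
    "write_dataset",
    "split",
    "difference",
]

FEATURE_KEYS = tuple(f"X{i}" for i in range(1, 18))
CALENDAR_KEYS = FEATURE_KEYS[:8]
METEO_KEYS = FEATURE_KEYS[8:]

#: Human-readable labels for reports.
FEATURE_LABELS = {
    "X1": "Year",
    "X2": "Semester",
    "X3": "Month of Year",
    "X4": "Day of Week",
    "X5": "Recode X4",
    "X6": "Holiday",
    "X7": "After Holiday",
    "X8": "Calendar Events",
    "X9": "Max. Temperature",
    "X10": "Min. Temperature",
    "X11": "Average Temperature",
    "X12": "Delta Temperature",
    "X13": "Max. Wind Speed",
    "X14": "Average Wind Speed",
    "X15": "Average Raining",
    "X16": "Average Humidity",
    "X17": "Sunny Hours",
}

# Allowed domains for the categorical calendar codes.
_CATEGORICAL_DOMAINS = {
    "X2": {1, 2},
    "X3": set(range(1, 13)),
    "X4": set(range(1, 8)),
    "X5": {0, 1},
    "X6": {0, 1},
    "X7": {0, 1},
    "X8": {0, 1, 2},
}


class SchemaError(ValueError):
    """A required column is missing or misnamed."""


class ValidationError(ValueError):
    """Row-level data violates an invariant (counts, dates, codes)."""


@dataclass(frozen=True)
class SplitSpec:
    """Contiguous train/test partition: first ``train_length`` days for
    fitting, the next ``test_length`` days held out."""

    train_length: int = 1008
    test_length: int = 84

    def __post_init__(self) -> None:
        if self.train_length <= 0 or self.test_length <= 0:
            raise ValueError("train_length and test_length must be positive")


class TimeSeriesDataset:
    """Ordered daily records: date, arrival count, and features X1-X17.

    Backed by a :class:`pandas.DataFrame` with columns
    ``date, y, X1..X17``; dates are strictly increasing by exactly one
    day (no gaps, no duplicates).
    """

    def __init__(self, frame: pd.DataFrame, name: str = "ed-series", validate: bool = True):
        frame = frame.copy()
        required = ["date", "y", *FEATURE_KEYS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        frame["date"] = pd.to_datetime(frame["date"])
        frame = frame.sort_values("date").reset_index(drop=True)
        self._frame = frame[required]
        self.name = name
        if validate:
            self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        f = self._frame
        if len(f) < 2:
            raise ValidationError("dataset must contain at least 2 days")
        deltas = f["date"].diff().dropna()
        bad = deltas[deltas != pd.Timedelta(days=1)]
        if len(bad):
            i = bad.index[0]
            raise ValidationError(
                f"dates must advance by exactly one day; offending gap between "
                f"{f['date'].iloc[i - 1].date()} and {f['date'].iloc[i].date()}"
            )
        y = f["y"].to_numpy()
        if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y != np.floor(y)):
            idx = int(np.where(~np.isfinite(y) | (y < 0) | (y != np.floor(y)))[0][0])
            raise ValidationError(f"arrival counts must be nonnegative integers (row {idx})")
        feats = f[list(FEATURE_KEYS)].to_numpy(dtype=float)
        if np.any(~np.isfinite(feats)):
            idx = int(np.where(~np.isfinite(feats).all(axis=1))[0][0])
            raise ValidationError(f"missing/non-finite feature value (row {idx})")
        for key, domain in _CATEGORICAL_DOMAINS.items():
            vals = set(np.unique(f[key].to_numpy()))
            extra = {v for v in vals if v not in domain}
            if extra:
                raise ValidationError(f"{key} contains out-of-domain codes: {sorted(extra)}")

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def dates(self) -> pd.Series:
        return self._frame["date"].copy()

    @property
    def arrivals(self) -> np.ndarray:
        """y_t as a float array (counts, but float for modelling)."""
        return self._frame["y"].to_numpy(dtype=float)

    def features(self, keys: Sequence[str] | None = None) -> pd.DataFrame:
        keys = list(keys) if keys is not None else list(FEATURE_KEYS)
        unknown = [k for k in keys if k not in FEATURE_KEYS]
        if unknown:
            raise SchemaError(f"unknown feature key(s): {', '.join(unknown)}")
        return self._frame[keys].copy()

    def head(self, n: int = 5) -> pd.DataFrame:
        return self._frame.head(n)

    def __repr__(self) -> str:
        d0 = self._frame["date"].iloc[0].date()
        d1 = self._frame["date"].iloc[-1].date()
        return f"TimeSeriesDataset({self.name!r}, n={len(self)}, {d0}..{d1})"


def read_dataset(
    path,
    column_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> TimeSeriesDataset:
    """Read a daily-arrivals CSV into a validated :class:`TimeSeriesDataset`.

    Parameters
    ----------
    path : str or path-like
        Comma-separated UTF-8 file with a header row naming a date
        column, an arrivals column and the 17 feature columns.
    column_map : mapping, optional
        ``{source_header: canonical_name}`` aliases so an arbitrary
        header layout can be bound to ``date``, ``y``, ``X1``..``X17``
        without editing the data file.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    dupes = frame["date"].duplicated() if "date" in frame.columns else None
    if dupes is not None and dupes.any():
        d = frame["date"][dupes].iloc[0]
        raise ValidationError(f"duplicated date in input: {d}")
    return TimeSeriesDataset(frame, name=name or str(path))


def write_dataset(ds: TimeSeriesDataset, path) -> None:
    """Write the canonical CSV layout (``date,y,X1..X17``)."""
    out = ds.frame
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def split(ds: TimeSeriesDataset, spec: SplitSpec) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Partition into the first ``train_length`` days and the following
    ``test_length`` days."""
    total = spec.train_length + spec.test_length
    if total > len(ds):
        raise IndexError(
            f"split ({spec.train_length} + {spec.test_length}) exceeds dataset length {len(ds)}"
        )
    f = ds.frame
    train = TimeSeriesDataset(f.iloc[: spec.train_length], name=f"{ds.name}[train]")
    test = TimeSeriesDataset(
        f.iloc[spec.train_length: total], name=f"{ds.name}[test]"
    )
    return train, test


def difference(series, d: int) -> np.ndarray:
    """d-th order differencing (1 - B)^d; d = 0 is the identity.

    Returns ``len(series) - d`` values.
    """
    arr = np.asarray(series, dtype=float)
    if d < 0:
        raise ValueError("differencing order must be nonnegative")
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(arr) <= d:
        raise IndexError(f"series of length {len(arr)} too short for d={d}")
    return np.diff(arr, n=d) if d > 0 else arr.copy()
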