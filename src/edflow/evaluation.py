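"""Forecast accuracy indices, the Diebold-Mariano test and horizon reports.

Seven indices over a held-out window: ME, RMSE, MAE (count units), MPE,
MAPE, SMAPE (percent) and R-squared. R-squared here is the coefficient
of determination of the least-squares scaling of observed on forecast
values — i.e. the squared Pearson correlation — not 1 - SSE/SST, which
is why a model can show a low R-squared next to a decent RMSE.

The DM statistic is applied per model against the actuals: with
d_t the per-day distance (signed error by default),
DM = mean(d) / (sd_pop(d) / sqrt(T)), with a two-sided standard-normal
p-value. Squared and absolute distances, a Harvey-Leybourne-Newbold
small-sample correction, and an autocorrelation-robust variance are
available behind flags but are off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HorizonSpec",
    "accuracy_indices",
    "dm_test",
    "compare_models",
    "report_to_markdown",
]

INDEX_COLUMNS = ["R2", "ME", "RMSE", "MAE", "MPE", "MAPE", "SMAPE", "DM", "p"]


@dataclass(frozen=True)
class HorizonSpec:
    """Named 1-based inclusive day ranges of the forecast window."""

    slices: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "short": (1, 28),
            "intermediate": (29, 56),
            "long": (57, 84),
            "overall": (1, 84),
        }
    )

    def validate(self, test_length: int) -> None:
        for name, (a, b) in self.slices.items():
            if not (1 <= a <= b <= test_length):
                raise ValueError(
                    f"horizon {name!r} = ({a}, {b}) does not fit test length {test_length}"
                )


def accuracy_indices(actual, forecast) -> dict[str, float]:
    """The seven-index suite for one actual/forecast pair."""
    y = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel()
    if len(y) != len(f):
        raise ValueError("actual and forecast lengths differ")
    if len(y) < 2:
        raise ValueError("need at least 2 forecast days")
    err = y - f
    if np.any(y == 0):
        raise ZeroDivisionError("zero actual value: percentage indices undefined")
    denom = (np.abs(y) + np.abs(f)) / 2.0
    ok = denom > 0
    if not ok.all():
        warnings.warn("zero |y|+|f| term skipped in SMAPE", stacklevel=2)
    if np.ptp(y) == 0 or np.ptp(f) == 0:
        r2 = 0.0 if np.ptp(f) == 0 and np.ptp(y) > 0 else 1.0
    else:
        r2 = float(np.corrcoef(y, f)[0, 1] ** 2)
    return {
        "R2": r2,
        "ME": float(np.mean(err)),
        "RMSE": float(np.sqrt(np.mean(err**2))),
        "MAE": float(np.mean(np.abs(err))),
        "MPE": float(100.0 * np.mean(err / y)),
        "MAPE": float(100.0 * np.mean(np.abs(err / y))),
        "SMAPE": float(100.0 * np.mean(np.abs(err[ok]) / denom[ok])),
    }


def dm_test(
    actual,
    forecast,
    distance: str = "signed",
    small_sample: bool = False,
    robust_variance: bool = False,
) -> tuple[float, float]:
    """Diebold-Mariano-type test of the forecast-actual discrepancy.

    ``distance``: 'signed' (default, d_t = y_t - f_t), 'absolute' or
    'squared'. Statistic = mean(d) * sqrt(T) / sd_pop(d); two-sided
    normal p. ``small_sample`` applies the Harvey-Leybourne-Newbold
    factor and a t(T-1) reference; ``robust_variance`` uses a
    Newey-West long-run variance with floor(T^(1/3)) lags.
    """
    y = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel()
    if len(y) != len(f):
        raise ValueError("actual and forecast lengths differ")
    T = len(y)
    if T < 3:
        raise ValueError("need at least 3 observations")
    err = y - f
    if distance == "signed":
        d = err
    elif distance == "absolute":
        d = np.abs(err)
    elif distance == "squared":
        d = err**2
    else:
        raise ValueError("distance must be 'signed', 'absolute' or 'squared'")
    dbar = d.mean()
    dev = d - dbar
    if robust_variance:
        L = int(np.floor(T ** (1 / 3)))
        var = dev @ dev / T
        for lag in range(1, L + 1):
            w = 1.0 - lag / (L + 1)
            var += 2.0 * w * (dev[lag:] @ dev[:-lag]) / T
        var = max(var, 1e-300)
    else:
        var = dev @ dev / T
    if var <= 0:
        raise ZeroDivisionError("distance series has zero variance: DM degenerate")
    stat = dbar / np.sqrt(var / T)
    if small_sample:
        h = 1
        corr = np.sqrt((T + 1 - 2 * h + h * (h - 1) / T) / T)
        stat *= corr
        p = 2.0 * stats.t.sf(abs(stat), T - 1)
    else:
        p = 2.0 * stats.norm.sf(abs(stat))
    return float(stat), float(p)


def compare_models(
    actual,
    forecasts: Mapping[str, Sequence[float]],
    horizons: HorizonSpec = HorizonSpec(),
    dm_distance: str = "signed",
) -> pd.DataFrame:
    """Full model x horizon accuracy cross-tabulation.

    Rows are (horizon, model); columns the seven indices plus the DM
    statistic (reported as magnitude) and its p-value. The best value
    per index within each horizon is flagged in ``*_best`` columns of
    the attrs dict. Raises if any forecast does not cover the window.
    """
    y = np.asarray(actual, dtype=float).ravel()
    horizons.validate(len(y))
    for name, f in forecasts.items():
        if len(np.asarray(f).ravel()) != len(y):
            raise ValueError(f"model {name!r} does not cover the full test window")
    rows = []
    for hname, (a, b) in horizons.slices.items():
        sl = slice(a - 1, b)
        for model, f in forecasts.items():
            fv = np.asarray(f, dtype=float).ravel()[sl]
            idx = accuracy_indices(y[sl], fv)
            try:
                stat, p = dm_test(y[sl], fv, distance=dm_distance)
                idx["DM"], idx["p"] = abs(stat), p
            except ZeroDivisionError:
                idx["DM"], idx["p"] = np.nan, np.nan
            rows.append({"horizon": hname, "model": model, **idx})
    report = pd.DataFrame(rows)[["horizon", "model", *INDEX_COLUMNS]]
    return report


def report_to_markdown(report: pd.DataFrame, decimals: int = 2) -> str:
    """Render the comparison report as a fixed-precision markdown table."""
    shown = report.copy()
    for c in INDEX_COLUMNS:
        shown[c] = shown[c].map(lambda v: f"{v:.{decimals}f}")
    header = "| " + " | ".join(shown.columns) + " |"
    sep = "|" + "|".join(["---"] * len(shown.columns)) + "|"
    lines = [header, sep]
    for _, row in shown.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)
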