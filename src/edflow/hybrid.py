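"""The two hybrid ARIMAX-ANN combination algorithms.

Hybrid 1 treats the series as an unknown function of four ingredients —
the ARIMAX fitted values L_t (linear component), a network fit to the
ARIMAX residuals N_t1, a network fit to the raw series N_t2, and the
exogenous features X_c left out of the ARIMAX — and learns the
combination y_t = f(L_t, N_t1, N_t2, X_c) with one more
single-hidden-layer network. At forecast time the residual stream is
iterated forward by feeding the network its own predicted residuals
(nothing from the test period is observed).

Hybrid 2 is the unweighted mean of the linear and nonlinear forecast
vectors, y_hat = (L_hat + N_hat) / 2; when the two components are
biased in opposite directions their errors cancel, and elementwise
|combined - y| <= max(|L_hat - y|, |N_hat - y|) always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import FEATURE_KEYS, TimeSeriesDataset
from .linear_models import ArimaxFit, forecast_arimax
from .neural_models import AnnConfig, AnnFit, fit_ann, forecast_ann

__all__ = ["Hybrid1Fit", "Hybrid2Forecast", "hybrid1_fit", "hybrid1_forecast",
           "hybrid2_forecast", "lag_matrix"]


def lag_matrix(series: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Design of ``n_lags`` trailing values per row; returns (X, target)
    aligned so row t predicts series[t] from series[t-n_lags .. t-1]."""
    s = np.asarray(series, dtype=float)
    if len(s) <= n_lags:
        raise ValueError("series too short for the requested lag count")
    X = np.column_stack([s[n_lags - k - 1: len(s) - k - 1] for k in range(n_lags)])
    return X, s[n_lags:]


@dataclass
class Hybrid1Fit:
    arimax_fit: ArimaxFit
    residual_net: AnnFit
    series_net: AnnFit
    combiner_net: AnnFit
    excluded_keys: tuple[str, ...]
    series_keys: tuple[str, ...]
    residual_lags: int
    fitted: np.ndarray            # aligned with training days residual_lags..n-1
    fit_offset: int               # index of the first combined fitted day
    _last_residuals: np.ndarray = None

    @property
    def combiner_inputs(self) -> int:
        return 3 + len(self.excluded_keys)


def hybrid1_fit(
    train: TimeSeriesDataset,
    arimax_fit: ArimaxFit,
    series_net: AnnFit,
    combiner_config: AnnConfig = AnnConfig(q_hidden=40),
    series_keys: tuple[str, ...] | None = None,
    excluded_keys: tuple[str, ...] | None = None,
    residual_lags: int = 7,
    residual_config: AnnConfig | None = None,
) -> Hybrid1Fit:
    """Assemble and train the four-ingredient combiner.

    ``series_net`` must already be fitted on ``train`` (its fitted
    values supply N_t2). The residual network uses one week of lagged
    ARIMAX residuals by default. ``excluded_keys`` defaults to the
    complement of the ARIMAX exogenous keys among X1-X17.
    """
    n = len(train)
    y = train.arrivals
    if len(arimax_fit.fitted) != n or len(series_net.fitted) != n:
        raise ValueError("component fits are not aligned with the training range")
    if excluded_keys is None:
        excluded_keys = tuple(k for k in FEATURE_KEYS if k not in arimax_fit.spec.exog_keys)
    series_keys = tuple(series_keys) if series_keys is not None else tuple(FEATURE_KEYS)

    resid = arimax_fit.residuals
    if n <= residual_lags + 5:
        raise ValueError("training series too short for the residual network")
    res_X, res_y = lag_matrix(resid, residual_lags)
    res_cfg = residual_config or AnnConfig(
        q_hidden=min(20, max(2, (n - residual_lags) // 10)),
        seed=combiner_config.seed + 1,
    )
    residual_net = fit_ann(res_X, res_y, res_cfg)

    off = residual_lags
    L = arimax_fit.fitted[off:]
    N1 = residual_net.fitted
    N2 = series_net.fitted[off:]
    Xc = train.features(excluded_keys).to_numpy(dtype=float)[off:]
    comb_X = np.column_stack([L, N1, N2, Xc])
    combiner_net = fit_ann(comb_X, y[off:], combiner_config)

    return Hybrid1Fit(
        arimax_fit=arimax_fit, residual_net=residual_net, series_net=series_net,
        combiner_net=combiner_net, excluded_keys=tuple(excluded_keys),
        series_keys=series_keys, residual_lags=residual_lags,
        fitted=combiner_net.fitted, fit_offset=off,
        _last_residuals=resid[-residual_lags:].copy(),
    )


def _recursive_residual_forecast(fit: Hybrid1Fit, h: int) -> np.ndarray:
    buf = list(fit._last_residuals)
    out = np.empty(h)
    for t in range(h):
        row = np.array(buf[-fit.residual_lags:][::-1])  # lag1 first
        pred = float(forecast_ann(fit.residual_net, row[None, :])[0])
        out[t] = pred
        buf.append(pred)
    return out


def hybrid1_forecast(fit: Hybrid1Fit, future_exog: pd.DataFrame, h: int) -> np.ndarray:
    """84-day-style out-of-sample forecast from the composite fit.

    L_hat comes from the ARIMAX forecast, N_hat2 from the series
    network on future features, N_hat1 from the residual network fed
    its own predictions recursively; the three streams plus the
    excluded features go through the combiner.
    """
    need = set(fit.arimax_fit.spec.exog_keys) | set(fit.excluded_keys) | set(fit.series_keys)
    missing = [k for k in sorted(need) if k not in future_exog.columns]
    if missing:
        raise KeyError(f"future exog missing column(s): {missing}")
    if len(future_exog) < h:
        raise ValueError("future exog shorter than requested horizon")
    fx = future_exog.iloc[:h]
    L = forecast_arimax(fit.arimax_fit, fx, h)
    N2 = forecast_ann(fit.series_net, fx[list(fit.series_keys)].to_numpy(dtype=float))
    N1 = _recursive_residual_forecast(fit, h)
    Xc = fx[list(fit.excluded_keys)].to_numpy(dtype=float)
    comb_X = np.column_stack([L, N1, N2, Xc])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return forecast_ann(fit.combiner_net, comb_X)


@dataclass(frozen=True)
class Hybrid2Forecast:
    linear: np.ndarray
    nonlinear: np.ndarray
    combined: np.ndarray


def hybrid2_forecast(linear, nonlinear) -> Hybrid2Forecast:
    """Elementwise mean of the linear and nonlinear forecast vectors."""
    L = np.asarray(linear, dtype=float).ravel()
    N = np.asarray(nonlinear, dtype=float).ravel()
    if len(L) != len(N):
        raise ValueError(f"forecast lengths differ: {len(L)} vs {len(N)}")
    return Hybrid2Forecast(linear=L, nonlinear=N, combined=(L + N) / 2.0)
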