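"""Stationarity testing, ARIMAX estimation/forecasting and the NB GLM baseline.

The ARIMAX is the regression-with-ARMA-errors form: the d-th difference
of (y_t - m_t) follows an ARMA(p, q), where m_t = c + sum_i eta_i x_it
is the exogenous regression. Estimation is full maximum likelihood via
``statsmodels.tsa.arima.model.ARIMA`` (which implements exactly this
form), with stationarity/invertibility enforced. The count baseline is
a negative-binomial GLM with log or identity link; the NB shape is
profiled out by scalar likelihood maximization and an overdispersion
likelihood-ratio test against Poisson is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.stattools import pacf as sm_pacf

from .core_data import FEATURE_KEYS, TimeSeriesDataset

__all__ = [
    "AdfResult",
    "ArimaxSpec",
    "ArimaxFit",
    "GlmFit",
    "adf_test",
    "correlogram",
    "fit_arimax",
    "select_order",
    "forecast_arimax",
    "fit_glm_nb",
    "forecast_glm",
]


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    p_value: float
    lags_used: int
    stationary: bool
    alpha: float


def adf_test(series, alpha: float = 0.05) -> AdfResult:
    """Augmented Dickey-Fuller unit-root test with automatic (AIC) lag
    choice; ``stationary`` flags p < alpha."""
    arr = np.asarray(series, dtype=float)
    if len(arr) < 20:
        raise ValueError("ADF needs at least 20 observations")
    if np.ptp(arr) == 0.0:
        raise ValueError("constant series: ADF is undefined")
    stat, p, lags, *_ = adfuller(arr, autolag="AIC")
    return AdfResult(float(stat), float(p), int(lags), bool(p < alpha), alpha)


def correlogram(series, n_lags: int = 40) -> dict:
    """Sample ACF and PACF with the +-1.96/sqrt(n) white-noise band."""
    arr = np.asarray(series, dtype=float)
    if n_lags >= len(arr) / 2:
        raise ValueError("n_lags must be below half the series length")
    if np.ptp(arr) == 0.0:
        raise ValueError("constant series: correlogram is undefined")
    a = sm_acf(arr, nlags=n_lags, fft=True)
    p = sm_pacf(arr, nlags=n_lags, method="ywm")
    return {"acf": a, "pacf": p, "band": 1.96 / np.sqrt(len(arr))}


@dataclass(frozen=True)
class ArimaxSpec:
    """Order (p, d, q) plus exogenous feature keys (b = len(exog_keys))."""

    p: int = 1
    d: int = 1
    q: int = 2
    exog_keys: tuple[str, ...] = ()
    include_constant: bool = True

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be nonnegative")
        object.__setattr__(self, "exog_keys", tuple(self.exog_keys))
        bad = [k for k in self.exog_keys if k not in FEATURE_KEYS]
        if bad:
            raise ValueError(f"unknown exogenous keys: {bad}")

    @property
    def b(self) -> int:
        return len(self.exog_keys)

    @property
    def n_params(self) -> int:
        return self.p + self.q + self.b + int(self.include_constant) + 1


@dataclass
class ArimaxFit:
    spec: ArimaxSpec
    phi: np.ndarray
    theta: np.ndarray
    eta: np.ndarray
    constant: float
    sigma2: float
    std_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    aic: float
    bic: float
    log_likelihood: float
    _results: object = field(repr=False, default=None)

    @property
    def exog_pvalues(self) -> dict[str, float]:
        return {k: self.p_values[k] for k in self.spec.exog_keys}


def _exog_matrix(ds: TimeSeriesDataset, keys: Sequence[str]) -> pd.DataFrame | None:
    return ds.features(keys) if keys else None


def fit_arimax(train: TimeSeriesDataset, spec: ArimaxSpec) -> ArimaxFit:
    """Maximum-likelihood ARIMAX fit on a training dataset."""
    n = len(train)
    if n <= spec.p + spec.q + spec.b + spec.d + 10:
        raise ValueError("training series too short for the requested order")
    y = train.arrivals
    exog = _exog_matrix(train, spec.exog_keys)
    if exog is not None:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), exog.to_numpy()]))
        if rank < exog.shape[1] + 1:
            raise ValueError(
                f"singular exogenous design among {list(spec.exog_keys)}"
            )
    trend = "c" if (spec.include_constant and spec.d == 0) else None
    model = ARIMA(
        y,
        exog=exog.to_numpy() if exog is not None else None,
        order=(spec.p, spec.d, spec.q),
        trend=trend,
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="statespace", method_kwargs={"maxiter": 500})
    retvals = res.mle_retvals
    if not retvals.get("converged", True):
        gnorm = float(np.max(np.abs(retvals.get("gopt", np.inf))))
        if gnorm > 1e-2:  # a flat stop near the optimum is fine
            raise RuntimeError(f"ARIMAX optimizer failed to converge: {retvals}")

    names = list(res.param_names)
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    pv = dict(zip(names, res.pvalues))

    def _rename(name: str) -> str:
        if name.startswith("ar.L"):
            return f"AR{name[4:]}"
        if name.startswith("ma.L"):
            return f"MA{name[4:]}"
        if name.startswith("x"):
            return spec.exog_keys[int(name[1:]) - 1]
        return {"const": "const", "intercept": "const", "sigma2": "sigma2"}.get(name, name)

    std_errors = {_rename(k): float(v) for k, v in bse.items()}
    p_values = {_rename(k): float(v) for k, v in pv.items()}
    phi = np.array([params[f"ar.L{i}"] for i in range(1, spec.p + 1)])
    theta = np.array([params[f"ma.L{i}"] for i in range(1, spec.q + 1)])
    eta = np.array([params[f"x{i}"] for i in range(1, spec.b + 1)])
    const = float(params.get("const", params.get("intercept", 0.0)))
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = y - fitted
    return ArimaxFit(
        spec=spec, phi=phi, theta=theta, eta=eta, constant=const,
        sigma2=float(params["sigma2"]), std_errors=std_errors, p_values=p_values,
        fitted=fitted, residuals=resid, aic=float(res.aic), bic=float(res.bic),
        log_likelihood=float(res.llf), _results=res,
    )


def select_order(
    train: TimeSeriesDataset,
    p_max: int = 3,
    d_max: int = 1,
    q_max: int = 3,
    exog_keys: Sequence[str] = (),
    criterion: str = "bic",
) -> ArimaxSpec:
    """Exhaustive (p, d, q) grid search minimizing AIC or BIC.

    Ties are broken toward fewer parameters; raises if no candidate
    converges.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    results = []
    attempted = []
    for p, d, q in product(range(p_max + 1), range(d_max + 1), range(q_max + 1)):
        spec = ArimaxSpec(p, d, q, tuple(exog_keys))
        attempted.append((p, d, q))
        try:
            fit = fit_arimax(train, spec)
        except Exception:
            continue
        score = fit.aic if criterion == "aic" else fit.bic
        results.append((score, spec.n_params, spec))
    if not results:
        raise RuntimeError(f"no ARIMAX spec converged; attempted {attempted}")
    results.sort(key=lambda r: (round(r[0], 6), r[1]))
    return results[0][2]


def forecast_arimax(fit: ArimaxFit, future_exog: pd.DataFrame | None, h: int | None = None) -> np.ndarray:
    """Dynamic multi-step forecast over h future days.

    Exogenous rows must cover every key in the fitted spec; no
    test-period observations are fed back. Deterministic given the fit.
    """
    keys = fit.spec.exog_keys
    if keys:
        if future_exog is None:
            raise ValueError("future exogenous rows are required by this fit")
        missing = [k for k in keys if k not in future_exog.columns]
        if missing:
            raise KeyError(f"future exog missing column(s): {missing}")
        ex = future_exog[list(keys)].to_numpy(dtype=float)
        steps = h if h is not None else len(ex)
        if len(ex) < steps:
            raise ValueError("future exog shorter than requested horizon")
        fc = fit._results.forecast(steps=steps, exog=ex[:steps])
    else:
        if h is None:
            raise ValueError("h is required when the fit has no exogenous features")
        fc = fit._results.forecast(steps=h)
    return np.asarray(fc, dtype=float)


# --------------------------------------------------------------------------
# Negative-binomial GLM baseline
# --------------------------------------------------------------------------

@dataclass
class GlmFit:
    family: str
    link: str
    exog_keys: tuple[str, ...]
    beta: Mapping[str, float]
    std_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    nb_alpha: float | None
    fitted: np.ndarray
    aic: float
    log_likelihood: float
    overdispersion_lr: float
    overdispersion_p: float
    _results: object = field(repr=False, default=None)


def _design(ds_or_frame, keys: Sequence[str]) -> np.ndarray:
    if isinstance(ds_or_frame, TimeSeriesDataset):
        X = ds_or_frame.features(keys).to_numpy(dtype=float)
    else:
        X = ds_or_frame[list(keys)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_glm_nb(
    train: TimeSeriesDataset,
    exog_keys: Sequence[str],
    link: str = "identity",
    family: str = "negative_binomial",
) -> GlmFit:
    """Count GLM for daily arrivals (Poisson or negative binomial).

    The NB shape parameter alpha (Var = mu + alpha mu^2) is profiled by
    scalar likelihood maximization. An overdispersion likelihood-ratio
    test of NB against Poisson is always computed (one-sided, boundary-
    corrected chi-square with 1 df).
    """
    if link not in ("log", "identity"):
        raise ValueError("link must be 'log' or 'identity'")
    if family not in ("poisson", "negative_binomial"):
        raise ValueError("family must be 'poisson' or 'negative_binomial'")
    keys = tuple(exog_keys)
    y = train.arrivals
    X = _design(train, keys)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    link_obj = sm.families.links.Log() if link == "log" else sm.families.links.Identity()

    start = None
    if link == "identity":
        start, *_ = np.linalg.lstsq(X, y, rcond=None)

    def _fit(fam):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=fam).fit(start_params=start, maxiter=300)

    pois = _fit(sm.families.Poisson(link_obj))

    def nb_nll(log_alpha: float) -> float:
        fam = sm.families.NegativeBinomial(link_obj, alpha=np.exp(log_alpha))
        try:
            return -_fit(fam).llf
        except Exception:
            return np.inf

    opt = optimize.minimize_scalar(nb_nll, bounds=(-12.0, 3.0), method="bounded",
                                   options={"xatol": 1e-4})
    alpha_hat = float(np.exp(opt.x))
    nb = _fit(sm.families.NegativeBinomial(link_obj, alpha=alpha_hat))

    lr = max(0.0, 2.0 * (nb.llf - pois.llf))
    over_p = 0.5 * stats.chi2.sf(lr, 1)

    res = nb if family == "negative_binomial" else pois
    names = ["const", *keys]
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if link == "identity" and np.any(fitted <= 0):
        raise ValueError("identity link produced nonpositive fitted means")
    return GlmFit(
        family=family, link=link, exog_keys=keys,
        beta=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, res.bse))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        nb_alpha=alpha_hat if family == "negative_binomial" else None,
        fitted=fitted, aic=float(res.aic), log_likelihood=float(res.llf),
        overdispersion_lr=float(lr), overdispersion_p=float(over_p),
        _results=res,
    )


def forecast_glm(fit: GlmFit, future_exog: pd.DataFrame) -> np.ndarray:
    """Inverse-link evaluation of the linear predictor on future rows."""
    missing = [k for k in fit.exog_keys if k not in future_exog.columns]
    if missing:
        raise KeyError(f"future exog missing column(s): {missing}")
    X = _design(future_exog, fit.exog_keys)
    pred = np.asarray(fit._results.predict(X), dtype=float)
    if fit.link == "identity" and np.any(pred <= 0):
        raise ValueError("identity link produced nonpositive predicted means")
    return pred
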