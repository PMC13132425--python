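"""Single-hidden-layer sigmoid network for the nonlinear component.

Two training modes are provided for the same architecture
``y_hat = w_out . g(W_in x + b) + w0`` with g the logistic sigmoid:

* ``elm`` (default): extreme learning machine — hidden weights and
  biases are drawn once from a seeded uniform(-1, 1) on min-max scaled
  inputs and frozen; the output weights are the minimum-norm
  least-squares solution of the hidden-activation system (pseudo-
  inverse). Deterministic and bit-reproducible given the seed.
* ``backprop``: full-batch gradient descent on squared error for a
  stated number of epochs.

Feature importance is the mean absolute analytic gradient of the
squared-error loss with respect to each raw input, normalized to
percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "sigmoid",
    "AnnConfig",
    "AnnFit",
    "fit_ann",
    "forecast_ann",
    "select_hidden_nodes",
    "feature_importance",
]


def sigmoid(z):
    """Overflow-safe logistic function 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AnnConfig:
    """Network structure and training choices.

    ``q_hidden`` defaults to 40 hidden nodes, the size selected for the
    ED series by validation RMSE. Inputs are min-max scaled to [0, 1]
    by default (z-scoring available); categorical codes enter as their
    integer values after scaling.
    """

    q_hidden: int = 40
    training_mode: str = "elm"
    epochs: int = 500
    learning_rate: float = 0.05
    input_scaling: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q_hidden < 1:
            raise ValueError("q_hidden must be >= 1")
        if self.training_mode not in ("elm", "backprop"):
            raise ValueError("training_mode must be 'elm' or 'backprop'")
        if self.input_scaling not in ("minmax", "zscore"):
            raise ValueError("input_scaling must be 'minmax' or 'zscore'")


@dataclass
class AnnFit:
    config: AnnConfig
    w_in: np.ndarray          # (q_hidden, n_features)
    b_hidden: np.ndarray      # (q_hidden,)
    w_out: np.ndarray         # (q_hidden,)
    w0: float                 # output intercept
    x_offset: np.ndarray
    x_scale: np.ndarray
    y_offset: float
    y_scale: float
    fitted: np.ndarray
    residuals: np.ndarray
    training_rmse: float
    n_features: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_features = self.w_in.shape[1]


def _fit_scaler(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "minmax":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0.0] = 1.0
        return lo, rng
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    return mu, sd


def _hidden(X_scaled: np.ndarray, w_in: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sigmoid(X_scaled @ w_in.T + b)


def fit_ann(inputs, target, config: AnnConfig = AnnConfig()) -> AnnFit:
    """Train the single-hidden-layer network on an (n, p) input matrix."""
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(y):
        raise ValueError("inputs and target lengths differ")
    if config.training_mode == "elm" and config.q_hidden >= n:
        raise ValueError(
            f"ELM with q_hidden={config.q_hidden} >= n={n} is ill-posed"
        )

    x_off, x_sc = _fit_scaler(X, config.input_scaling)
    Xs = (X - x_off) / x_sc
    y_off = float(y.min())
    y_sc = float(np.ptp(y)) or 1.0
    ys = (y - y_off) / y_sc

    rng = np.random.default_rng(config.seed)
    q = config.q_hidden
    w_in = rng.uniform(-1.0, 1.0, size=(q, p))
    b = rng.uniform(-1.0, 1.0, size=q)

    H = _hidden(Xs, w_in, b)
    if config.training_mode == "elm":
        Ha = np.column_stack([np.ones(n), H])
        if np.linalg.matrix_rank(Ha) < min(Ha.shape):
            warnings.warn("rank-deficient hidden matrix: minimum-norm solution used",
                          stacklevel=2)
        coef, *_ = np.linalg.lstsq(Ha, ys, rcond=None)
        w0, w_out = float(coef[0]), coef[1:]
    else:
        w_out = rng.normal(0.0, 0.1, size=q)
        w0 = 0.0
        lr = config.learning_rate
        for _ in range(config.epochs):
            pred = H @ w_out + w0
            err = pred - ys                        # (n,)
            g_out = H.T @ err / n
            g_w0 = err.mean()
            delta = (err[:, None] * w_out) * H * (1 - H)   # (n, q)
            g_in = delta.T @ Xs / n
            g_b = delta.mean(axis=0)
            w_out -= lr * g_out
            w0 -= lr * g_w0
            w_in -= lr * g_in
            b -= lr * g_b
            H = _hidden(Xs, w_in, b)

    fitted = (H @ w_out + w0) * y_sc + y_off
    resid = y - fitted
    return AnnFit(
        config=config, w_in=w_in, b_hidden=b, w_out=w_out, w0=w0,
        x_offset=x_off, x_scale=x_sc, y_offset=y_off, y_scale=y_sc,
        fitted=fitted, residuals=resid,
        training_rmse=float(np.sqrt(np.mean(resid**2))),
    )


def forecast_ann(fit: AnnFit, future_inputs) -> np.ndarray:
    """Evaluate the trained network on new rows (deterministic)."""
    X = np.asarray(future_inputs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != fit.n_features:
        raise ValueError(
            f"expected {fit.n_features} input column(s), got {X.shape[1]}"
        )
    Xs = (X - fit.x_offset) / fit.x_scale
    if fit.config.input_scaling == "minmax" and (Xs.min() < -0.5 or Xs.max() > 1.5):
        warnings.warn("inputs far outside the training range: extrapolating",
                      stacklevel=2)
    H = _hidden(Xs, fit.w_in, fit.b_hidden)
    return (H @ fit.w_out + fit.w0) * fit.y_scale + fit.y_offset


def select_hidden_nodes(inputs, target, q_grid, config: AnnConfig = AnnConfig()) -> int:
    """Pick the hidden-layer size minimizing validation RMSE.

    The last 20% of rows are held out; ties break toward the smaller
    size."""
    q_grid = sorted(set(int(q) for q in q_grid))
    if not q_grid:
        raise ValueError("empty hidden-node grid")
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    cut = max(1, int(round(n * 0.8)))
    best_q, best_rmse = None, np.inf
    for q in q_grid:
        cfg = AnnConfig(q_hidden=q, training_mode=config.training_mode,
                        epochs=config.epochs, learning_rate=config.learning_rate,
                        input_scaling=config.input_scaling, seed=config.seed)
        try:
            fit = fit_ann(X[:cut], y[:cut], cfg)
        except Exception:
            continue
        pred = forecast_ann(fit, X[cut:])
        rmse = float(np.sqrt(np.mean((y[cut:] - pred) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_q, best_rmse = q, rmse
    if best_q is None:
        raise RuntimeError(f"no hidden-node size in {q_grid} produced a fit")
    return best_q


def feature_importance(fit: AnnFit, inputs, target) -> np.ndarray:
    """Gradient-based relative importance of each raw input, in percent.

    importance_i = mean_t | dL_t/dx_i | with L_t the squared error at
    row t, the derivative taken analytically through the sigmoid layer
    (and the input scaler); normalized to sum to 100.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    Xs = (X - fit.x_offset) / fit.x_scale
    H = _hidden(Xs, fit.w_in, fit.b_hidden)                  # (n, q)
    pred = (H @ fit.w_out + fit.w0) * fit.y_scale + fit.y_offset
    # dL/dx_i = -2 (y - yhat) * y_scale * sum_j w_j h_j (1-h_j) W_ji / x_scale_i
    dyhat_dxs = (H * (1 - H) * fit.w_out) @ fit.w_in          # (n, p), wrt scaled x
    grad = (-2.0 * (y - pred))[:, None] * fit.y_scale * dyhat_dxs / fit.x_scale
    raw = np.mean(np.abs(grad), axis=0)
    total = raw.sum()
    if total == 0.0:
        warnings.warn("zero total gradient: uniform attribution", stacklevel=2)
        return np.full(X.shape[1], 100.0 / X.shape[1])
    return 100.0 * raw / total
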