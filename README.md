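# edflow — hybrid ARIMAX–ANN forecasting of daily ED arrivals

Emergency departments plan staffing and supplies around tomorrow's
patient load, but daily arrival counts at a busy referral hospital are
driven by a tangle of calendar effects (weekends, holidays, religious
and traditional events, semester rhythms) and weather (temperature,
humidity, rain, sun), with both linear and nonlinear footprints.
`edflow` is a library for hospital statisticians and operations
researchers that implements a complete forecasting protocol for such
series: nonlinear association screening, a linear time-series model, a
neural model, two hybrid combinations of the two, a count-GLM
baseline, and a multi-horizon evaluation suite — plus a synthetic-data
generator so the entire pipeline is testable without access to any
hospital's records.

## The models

**Screening.** Each of 17 exogenous features is scored against the
arrival counts with the maximal information coefficient
(MIC ∈ [0, 1]), the largest normalized mutual information over data-
driven grids with at most n^0.6 cells (MINE approximation, implemented
from scratch, numba-accelerated). Permutation p-values are adjusted by
Benjamini–Hochberg (BH) and by the harmonic-penalty step-up
("M-FDR", valid under arbitrary dependence); forward selection admits
features in descending-MIC order while their ARIMAX coefficients stay
significant.

**ARIMAX(p, d, q, b)** in regression-with-ARMA-errors form:

    ∇^d (y_t − m_t) = ε_t + Σ_{i=1..p} φ_i ∇^d(y_{t−i} − m_{t−i}) + Σ_{j=1..q} θ_j ε_{t−j}
    m_t = c + Σ_{i=1..b} η_i x_it

estimated by full maximum likelihood (statsmodels ARIMA backend), with
ADF stationarity tests, ACF/PACF correlograms and AIC/BIC order search.

**ANN.** A single-hidden-layer sigmoid network
ŷ_t = Σ_j w_j · g(b_j + Σ_i w_ij x_i), trained either as an extreme
learning machine (random frozen hidden layer, least-squares output
weights — the default, bit-reproducible from a seed) or by
back-propagation. Gradient-based feature importance reports
mean |∂L/∂x_i| as percentages.

**Hybrids.** Hybrid1 learns y_t = f(L_t, N_t1, N_t2, X_c) with one
more network over the ARIMAX fitted values L_t, a network fit to the
ARIMAX residuals N_t1, the series network's fitted values N_t2 and the
features X_c the ARIMAX excluded. Hybrid2 is the unweighted mean
ŷ = (L̂ + N̂)/2, whose error can never exceed the worse component's on
any day and which cancels opposite-signed biases.

**Evaluation.** ME, RMSE, MAE, MPE, MAPE, SMAPE and R² (squared
correlation of observed with forecast) over short (days 1–28),
intermediate (29–56), long (57–84) and overall horizons, each with a
Diebold–Mariano-type z-test of the forecast–actual discrepancy.

## Worked example

```python
import numpy as np
from edflow import (GeneratorConfig, SplitSpec, ArimaxSpec, generate_arrivals,
                    split, fit_arimax, forecast_arimax, accuracy_indices)

ds = generate_arrivals(GeneratorConfig(n_days=1092, seed=42))
train, test = split(ds, SplitSpec(1008, 84))
fit = fit_arimax(train, ArimaxSpec(1, 1, 2, ("X2", "X5", "X6", "X7", "X8", "X11")))
print(round(fit.eta[0], 1), round(fit.eta[5], 2))   # -36.7 3.27
fc = forecast_arimax(fit, test.features(), 84)
print(round(accuracy_indices(test.arrivals, fc)["RMSE"], 1))  # 66.1
```

The semester coefficient −36.7 and temperature coefficient +3.27/°C
recover the planted effects (−35.4 and +3.37); the 84-day RMSE of 66.1
sits near the world's negative-binomial noise floor, i.e. the
exogenous structure is being captured and what remains is count noise.
The `examples/` directory walks through every capability the same way:

- `01_generate_and_describe.py` — synthetic world + descriptives
- `02_screen_features.py` — MIC table with BH / M-FDR flags
- `03_fit_arimax.py` — ADF, ARIMAX coefficients, 84-day forecast
- `04_ann_elm_importance.py` — ELM training, node selection, importance
- `05_hybrids_and_evaluation.py` — both hybrids + the full horizon table

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end experiment from scratch at full
protocol scale (1008 train / 84 test days, 40 hidden nodes, 199
screening permutations): it generates the synthetic series, screens
features, fits ARIMAX/ANN/GLM and both hybrids, forecasts the held-out
84 days, prints the per-horizon accuracy table, and writes the
acceptance JSON to `--out`.
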