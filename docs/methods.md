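# Methods

This note records the models implemented in `edflow`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that an auditor would want spelled
out.

## Data model

One row per calendar day: an arrival count `y` and 17 features. X1–X8
are calendar codes (year; semester; month; day-of-week 1=Sat..7=Fri;
a two-level weekday recode with Thu/Fri/Sat high; holiday;
after-holiday; event class 0/1/2), X9–X17 meteorological reals (max /
min / mean temperature °C, daily temperature range, max / mean wind
km/h, mean rain mm, mean relative humidity %, sunny hours). Dates must
advance by exactly one day; counts must be nonnegative integers;
missing values are rejected rather than imputed, because the protocol
this package implements assumes a complete registry extract. An alias
map in `read_dataset` binds arbitrary CSV headers to the canonical
names, since external files rarely use X1..X17 literally.

## MIC screening

MIC is computed with the MINE approximation: for each row count q the
y-axis is equipartitioned (ties never split); the x-axis partition is
then optimized exactly by dynamic programming over clumps — maximal
x-runs of points within one row, with tied x-values kept together and
mixed tie-groups isolated — capped at `max_clumps` (15) times the
column budget via superclump merging; both orientations are searched
and the best I/log(min(k, q)) over all grids with k·q ≤ n^0.6 wins.
The DP minimizes the unnormalized conditional entropy
Σ_cols n_col·H(rows | col), which makes the column cost additive and
the recursion exact for a fixed row partition. The kernels are
numba-jitted; a full 17-feature screen with 199 permutations on a
1092-day series takes on the order of 1–2 minutes on one CPU.

Tests validate the implementation against a brute-force enumeration of
*all* grids at tiny n (the approximation can never exceed it and must
match it on cleanly separable data), plus the standard invariances:
symmetry, invariance under strictly monotone transforms, saturation at
1.0 for noiseless functional data, and a constant input returning 0
with a warning.

Permutation p-values use p = (1 + #{MIC_perm ≥ MIC_obs})/(B + 1) with
a seeded generator; the library default is B = 999, while the pipeline
and the test battery use 199 as a runtime compromise (p-granularity
1/200 is ample at α = 0.05, but note the p floor of 1/(B+1) interacts
with the harmonic penalty: at B = 99 the floor 0.01 can leave *no*
feature M-FDR-significant at α = 0.05 with 17 features).

**M-FDR.** The dependency-penalized adjustment is realized as the
harmonic-sum step-up (BH values × c(m) = Σ 1/i, capped at 1) — the
classical correction valid under arbitrary dependence. It dominates BH
elementwise, so it can only flag fewer features; this ordering is a
tested invariant. The correction is isolated in `adjust_mfdr` and
trivially replaceable if a different dependency penalty is preferred.

**Forward selection** orders M-FDR-significant candidates by
descending MIC (ties by feature index) and keeps a candidate only if
all retained coefficients stay Wald-significant (p < 0.05) in the
working ARIMAX — "significant" is not further specified by the
protocol, so the Wald test on the ML fit is used.

## ARIMAX

Regression with ARMA errors (not the transfer-function variant): the
exogenous part m_t = c + Ση_i x_it is subtracted before the ARMA
recursion on the d-th difference. `statsmodels.tsa.arima.model.ARIMA`
implements exactly this form and provides full-ML estimation with
stationarity/invertibility enforced by parameter transformation;
coefficients, standard errors, Wald p-values, AIC/BIC and dynamic
multi-step forecasts are surfaced. With d ≥ 1 no constant is included
(it would become a drift). The optimizer runs LBFGS with maxiter 500;
a "not converged" flag with a gradient below 1e-2 is accepted, since
LBFGS frequently reports flat stops at the optimum. Seasonal orders
are deliberately absent: the weekly pattern is carried by the
day-of-week features. Forecasting is ex-post — test-period exogenous
rows are the actual recorded values, matching a held-out evaluation
where the calendar is known and weather is observed.

`select_order` is an exhaustive (p, d, q) grid search by AIC or BIC
with ties broken toward fewer parameters; non-converging cells are
skipped and reported if nothing converges.

## Negative-binomial GLM

The count baseline fits a GLM with Poisson or NB(α) family and log or
identity link. The NB shape α (Var = μ + αμ²) is profiled out by
bounded scalar likelihood maximization (log-α on [−12, 3]); identity-
link fits start from OLS coefficients and must produce strictly
positive means. Overdispersion is tested by the boundary-corrected
likelihood ratio of NB against Poisson (p = ½·χ²₁ tail), which keeps
its size on equidispersed data (tested).

## ELM / backprop network

One hidden sigmoid layer plus an output intercept. ELM mode draws
hidden weights and biases from uniform(−1, 1) on min-max-scaled
inputs (the reference estimator's distribution is unspecified;
uniform(−1, 1) is the customary ELM choice), then solves the output
layer by minimum-norm least squares — rank deficiency degrades to the
pseudo-inverse with a warning rather than an error. The target is
min-max scaled too, so a constant target is fit exactly through the
intercept. Backprop mode is full-batch gradient descent on the same
architecture. Hidden-node selection holds out the last 20% of training
rows and minimizes validation RMSE, ties toward the smaller size; the
protocol's chosen width for the ED series is 40.

Feature importance is mean |∂L/∂x_i| of the squared-error loss,
differentiated analytically through the output scaling, sigmoid layer
and input scaler (so it is a gradient with respect to the *raw*
feature); normalized to sum to 100. The analytic gradient is tested
against central finite differences at 1e-5 relative tolerance.
Categorical features enter as scaled integer codes, mirroring common
practice in the reference tooling.

## Hybrids

*Hybrid1* builds its residual network on 7 lags of the ARIMAX
residuals — one week, chosen because the protocol only says "a network
on the residuals"; the lag count is configurable. The combiner network
takes [L_t, N_t1, N_t2, X_c] (raw value streams, jointly min-max
scaled; X_c defaults to the 17-minus-ARIMAX-keys complement) with 40
hidden nodes. At forecast time the residual stream is iterated by
feeding the network its own predictions from the last 7 training
residuals — the protocol defines only the in-sample fit, and this
recursive scheme is this package's explicit choice to keep the
84-day evaluation honestly out-of-sample. Long-horizon users should
expect the recursion to decay toward the residual mean.

*Hybrid2* is exactly (L̂ + N̂)/2 — no optimized weights, which would be
a different method. Two consequences are tested: per-day
|combined − y| ≤ max component error (hence the RMSE of the
combination never exceeds the worse component, by the triangle
inequality), and bias cancellation when the components err in
opposite directions.

## Accuracy indices and the DM test

ME, RMSE, MAE in count units; MPE/MAPE/SMAPE in percent with SMAPE
terms scaled by (|y|+|ŷ|)/2 (zero-denominator terms are skipped with a
warning); R² is the squared Pearson correlation of observed with
forecast — the goodness of the least-squares scaling of one onto the
other — *not* 1 − SSE/SST, which is why low R² can coexist with decent
RMSE. Percentage indices are rendered to 2 decimals by the report
writer.

The DM statistic is d̄/(sd_pop(d)/√T) on a per-day distance series
against the actuals, with a two-sided standard-normal p. The default
distance is the signed error y_t − ŷ_t: the published usage this
reproduces reports |DM| values that are only consistent with the
signed error (they equal |ME|·√T/√(RMSE²−ME²) at every horizon),
whereas an absolute-error distance would make the statistic a large
positive number for any model. Absolute and squared distances, the
Harvey–Leybourne–Newbold small-sample factor and a Newey–West variance
are available behind flags and off by default. The plain statistic's
size on iid mean-zero distances is verified by simulation (2000 reps,
T = 200, rejection rate in [0.03, 0.08]).

## Synthetic generator

The generator emulates: NB-dispersed counts (size default 80, so the
marginal SD is ≈ 69 at mean 585, matching the documented dispersion of
the target series); weekly structure via the day-of-week recode;
semester seasonality; i.i.d. Bernoulli holidays (rate 0.08 ≈ 29/year)
with post-holiday flags and event classes on a 0.7 subset of holidays;
an annual temperature sinusoid (mean 15 °C, amplitude 13, peak near
midsummer) with coupled humidity/rain/sun; additive mean effects with
defaults equal to the fitted unstandardized ARIMAX coefficients of the
reference series; and a latent Gaussian AR(1) disturbance
(coefficient default 0.862, innovation SD 8). One global seed spawns
independent substreams for calendar, weather, disturbance and counts,
so changing one block's parameters never perturbs another's draws.

It does **not** emulate: the New-Year (Nowruz) spike shape and its
post-holiday collapse, autocorrelated holiday clustering, weather
extremes/regime changes, or any trend across years. Consequently a
green pipeline run establishes that the machinery is correct and that
planted parameters are recoverable — it does not certify accuracy
numbers on any real hospital's data.

Two calibration notes. (i) With the default innovation SD of 8 the
latent AR(1) is faint relative to the count noise (SD ≈ 69), so the
AR coefficient is *not* estimable from the default world — recovery
tests use a world with innovation SD 25 and NB size 2000, where the
AR(1)-plus-noise process is a well-identified ARMA(1,1). (ii) The
bias-cancellation demonstration denies the linear model the
temperature block and places the test window in the rising-temperature
season, making the linear model underestimate while the
feature-complete network does not — the mechanism, made reproducible.

## Known limitations

- MIC p-values are permutation-based and inherit the 1/(B+1) floor.
- The ARIMAX likelihood surface for over-differenced specs can have
  local optima; `select_order` mitigates this across the grid but a
  single requested spec may land badly on an unlucky sample.
- Hybrid1's recursive residual stream reverts to the mean within a few
  weeks; its long-horizon value comes from the other three inputs.
- The identity-link NB GLM can fail on worlds where the linear
  predictor goes nonpositive; the log link is the robust fallback.
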