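import numpy as np
import pandas as pd
import pytest

from edflow.core_data import SplitSpec, split
from edflow.linear_models import (
    ArimaxSpec,
    adf_test,
    correlogram,
    fit_arimax,
    fit_glm_nb,
    forecast_arimax,
    forecast_glm,
    select_order,
)
from edflow.synthetic import GeneratorConfig, generate_arrivals
from conftest import make_dataset


def ar1_series(phi, n, seed, sd=1.0):
    g = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = g.normal(0, sd / np.sqrt(1 - phi**2))
    for i in range(1, n):
        x[i] = phi * x[i - 1] + g.normal(0, sd)
    return x


class TestAdf:
    def test_random_walks_keep_their_unit_root(self):
        flags = []
        for seed in range(8):
            rw = np.cumsum(np.random.default_rng(seed).normal(size=500))
            flags.append(adf_test(rw).stationary)
        assert sum(flags) <= 1  # the test should almost never reject a unit root

    def test_white_noise_is_declared_stationary(self):
        flags = [
            adf_test(np.random.default_rng(100 + s).normal(size=500)).stationary
            for s in range(8)
        ]
        assert sum(flags) >= 7

    def test_differenced_synthetic_series_is_stationary(self, synth_ds):
        d1 = np.diff(synth_ds.arrivals)
        res = adf_test(d1)
        assert res.stationary and res.p_value < 0.01

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adf_test(np.ones(100))


class TestCorrelogram:
    def test_acf_lag0_is_one(self, rng):
        out = correlogram(rng.normal(size=300), 20)
        assert out["acf"][0] == pytest.approx(1.0)

    def test_white_noise_band_coverage(self):
        g = np.random.default_rng(7)
        out = correlogram(g.normal(size=1000), 40)
        outside = np.sum(np.abs(out["acf"][1:]) > out["band"])
        assert outside <= 5  # ~5% of 40 lags expected outside the 95% band

    def test_ar1_acf_geometric_and_pacf_cutoff(self):
        x = ar1_series(0.8, 4000, seed=3)
        out = correlogram(x, 10)
        acf, pacf = out["acf"], out["pacf"]
        for k in (1, 2, 3):
            assert acf[k] == pytest.approx(0.8**k, abs=0.08)
        assert pacf[1] == pytest.approx(0.8, abs=0.05)
        assert np.all(np.abs(pacf[2:6]) < 0.08)

    def test_nlags_bound(self, rng):
        with pytest.raises(ValueError):
            correlogram(rng.normal(size=40), 25)


class TestArimax:
    def test_pure_ar1_parameter_recovery(self):
        x = ar1_series(0.6, 1000, seed=11)
        ds = make_dataset(np.round(x * 10 + 500).astype(int))
        fit = fit_arimax(ds, ArimaxSpec(1, 0, 0, (), include_constant=True))
        assert abs(fit.phi[0] - 0.6) < 3 * fit.std_errors["AR1"]

    def test_degenerate_constant_only_model(self, rng):
        y = np.round(rng.normal(500, 20, 300)).astype(int)
        ds = make_dataset(y)
        fit = fit_arimax(ds, ArimaxSpec(0, 0, 0, ()))
        assert fit.constant == pytest.approx(y.mean(), rel=1e-3)
        assert fit.sigma2 == pytest.approx(y.var(), rel=0.05)

    def test_fitted_plus_residuals_reconstruct_series(self, synth_ds):
        train, _ = split(synth_ds, SplitSpec(300, 84))
        fit = fit_arimax(train, ArimaxSpec(1, 1, 1, ("X5", "X6")))
        assert np.allclose(fit.fitted + fit.residuals, train.arrivals)

    def test_collinear_exog_rejected(self, synth_ds):
        train, _ = split(synth_ds, SplitSpec(200, 84))
        # X12 = X9 - X10 exactly: singular design
        with pytest.raises(ValueError, match="singular"):
            fit_arimax(train, ArimaxSpec(1, 0, 0, ("X9", "X10", "X12")))

    def test_nested_models_never_lose_likelihood(self, synth_ds):
        train, _ = split(synth_ds, SplitSpec(400, 84))
        small = fit_arimax(train, ArimaxSpec(1, 0, 0, ()))
        large = fit_arimax(train, ArimaxSpec(1, 0, 1, ("X5",)))
        assert large.log_likelihood >= small.log_likelihood - 1e-6

    def test_too_short_series_rejected(self):
        ds = make_dataset(range(12))
        with pytest.raises(ValueError, match="too short"):
            fit_arimax(ds, ArimaxSpec(2, 1, 2, ("X5", "X6")))


class TestSelectOrder:
    def test_grid_of_one_returns_that_spec(self, synth_ds):
        train, _ = split(synth_ds, SplitSpec(250, 84))
        spec = select_order(train, p_max=1, d_max=0, q_max=0)
        assert (spec.p, spec.d, spec.q) in {(0, 0, 0), (1, 0, 0)}

    def test_bic_identifies_ar1_structure(self):
        x = ar1_series(0.7, 800, seed=5, sd=3.0)
        ds = make_dataset(np.round(x * 5 + 500).astype(int))
        spec = select_order(ds, p_max=2, d_max=0, q_max=2, criterion="bic")
        assert spec.p >= 1  # autoregression detected

    def test_white_noise_prefers_empty_model(self):
        g = np.random.default_rng(9)
        ds = make_dataset(np.round(g.normal(500, 10, 600)).astype(int))
        spec = select_order(ds, p_max=2, d_max=0, q_max=2, criterion="bic")
        assert (spec.p, spec.q) == (0, 0)


class TestForecastArimax:
    def test_constant_only_forecast_is_flat(self, rng):
        ds = make_dataset(np.round(rng.normal(500, 5, 200)).astype(int))
        fit = fit_arimax(ds, ArimaxSpec(0, 0, 0, ()))
        fc = forecast_arimax(fit, None, 10)
        assert np.allclose(fc, fit.constant)

    def test_ar1_forecast_decays_geometrically(self):
        x = ar1_series(0.7, 600, seed=13, sd=2.0)
        ds = make_dataset(np.round(x * 10 + 500).astype(int))
        fit = fit_arimax(ds, ArimaxSpec(1, 0, 0, ()))
        fc = forecast_arimax(fit, None, 20)
        mean = fit.constant
        ratios = (fc[1:] - mean) / (fc[:-1] - mean)
        assert np.allclose(ratios, fit.phi[0], atol=1e-6)

    def test_missing_future_exog_column_raises(self, synth_ds):
        train, test = split(synth_ds, SplitSpec(300, 84))
        fit = fit_arimax(train, ArimaxSpec(1, 0, 0, ("X6",)))
        with pytest.raises(KeyError, match="X6"):
            forecast_arimax(fit, test.features(["X5"]), 84)


class TestGlm:
    def test_intercept_only_poisson_log_closed_form(self, rng):
        y = rng.poisson(40, 400)
        ds = make_dataset(y)
        fit = fit_glm_nb(ds, (), link="log", family="poisson")
        assert fit.beta["const"] == pytest.approx(np.log(y.mean()), abs=1e-6)

    def test_nb_identity_recovers_planted_effect(self):
        cfg = GeneratorConfig(
            n_days=1008, effects={"X6": 25.0}, ar_coefficient=0.0,
            ar_innovation_sd=0.0, nb_dispersion=80.0, holiday_rate=0.15, seed=31,
        )
        ds = generate_arrivals(cfg)
        fit = fit_glm_nb(ds, ("X6",), link="identity")
        assert abs(fit.beta["X6"] - 25.0) < 3 * fit.std_errors["X6"]
        assert fit.overdispersion_p < 0.01  # NB data flags overdispersion

    def test_equidispersed_poisson_overdispersion_size(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(200 + seed)
            ds = make_dataset(g.poisson(500, 300))
            fit = fit_glm_nb(ds, (), link="log")
            hits += fit.overdispersion_p < 0.05
        assert hits <= 1  # test keeps its size on equidispersed data

    def test_forecast_is_inverse_link_of_predictor(self, rng):
        cfg = GeneratorConfig(n_days=300, seed=33)
        ds = generate_arrivals(cfg)
        fit = fit_glm_nb(ds, ("X5", "X11"), link="identity")
        fut = ds.features().iloc[:5]
        fc = forecast_glm(fit, fut)
        manual = (fit.beta["const"]
                  + fit.beta["X5"] * fut["X5"].to_numpy()
                  + fit.beta["X11"] * fut["X11"].to_numpy())
        assert np.allclose(fc, manual)
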