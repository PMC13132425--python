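import numpy as np
import pytest

from edflow.neural_models import (
    AnnConfig,
    feature_importance,
    fit_ann,
    forecast_ann,
    select_hidden_nodes,
    sigmoid,
)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry(self, rng):
        z = rng.normal(0, 5, 50)
        assert np.allclose(sigmoid(z) + sigmoid(-z), 1.0)

    def test_saturation_without_overflow(self):
        with np.errstate(over="raise"):
            assert sigmoid(40.0) == pytest.approx(1.0)
            assert sigmoid(-40.0) == pytest.approx(0.0)
            assert sigmoid(1000.0) == 1.0


class TestFitAnn:
    def test_constant_target_fit_exactly(self, rng):
        X = rng.normal(size=(80, 3))
        fit = fit_ann(X, np.full(80, 7.25), AnnConfig(q_hidden=5, seed=0))
        assert fit.training_rmse < 1e-8
        assert np.allclose(fit.fitted, 7.25)

    def test_realizable_sigmoid_mixture_is_learned(self, rng):
        X = rng.uniform(-2, 2, size=(500, 2))
        noise_sd = 0.05
        y = (1.5 * sigmoid(0.8 * X[:, 0] - 0.3 * X[:, 1] + 0.2)
             - 2.0 * sigmoid(-0.5 * X[:, 0] + 0.9 * X[:, 1])
             + rng.normal(0, noise_sd, 500))
        fit = fit_ann(X, y, AnnConfig(q_hidden=10, seed=1))
        assert fit.training_rmse < noise_sd * 1.5

    def test_capacity_improves_in_sample_fit(self, rng):
        X = rng.normal(size=(300, 17))
        y = np.sin(X[:, 0] * 2) + X[:, 1] ** 2 + rng.normal(0, 0.1, 300)
        small = fit_ann(X, y, AnnConfig(q_hidden=1, seed=2))
        large = fit_ann(X, y, AnnConfig(q_hidden=40, seed=2))
        assert large.training_rmse < small.training_rmse

    def test_same_seed_bit_identical(self, rng):
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        a = fit_ann(X, y, AnnConfig(q_hidden=8, seed=9))
        b = fit_ann(X, y, AnnConfig(q_hidden=8, seed=9))
        assert np.array_equal(a.w_in, b.w_in)
        assert np.array_equal(a.w_out, b.w_out)
        assert np.array_equal(a.fitted, b.fitted)

    def test_elm_overparameterized_rejected(self, rng):
        with pytest.raises(ValueError, match="ill-posed"):
            fit_ann(rng.normal(size=(20, 2)), rng.normal(size=20),
                    AnnConfig(q_hidden=25, seed=0))

    def test_backprop_reduces_loss(self, rng):
        X = rng.uniform(-1, 1, size=(200, 2))
        y = X[:, 0] * 2 + rng.normal(0, 0.1, 200)
        short = fit_ann(X, y, AnnConfig(q_hidden=6, training_mode="backprop",
                                        epochs=5, seed=3))
        long = fit_ann(X, y, AnnConfig(q_hidden=6, training_mode="backprop",
                                       epochs=800, seed=3))
        assert long.training_rmse < short.training_rmse

    def test_elm_rmse_nonincreasing_in_capacity_on_average(self, rng):
        X = rng.normal(size=(250, 5))
        y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.2, 250)
        rmse = {q: np.mean([fit_ann(X, y, AnnConfig(q_hidden=q, seed=s)).training_rmse
                            for s in range(10)])
                for q in (2, 10, 40)}
        assert rmse[40] <= rmse[10] <= rmse[2]


class TestForecastAnn:
    def test_training_row_reproduces_fitted_value(self, rng):
        X = rng.normal(size=(120, 3))
        y = rng.normal(size=120)
        fit = fit_ann(X, y, AnnConfig(q_hidden=7, seed=4))
        assert forecast_ann(fit, X[10:11])[0] == pytest.approx(fit.fitted[10])

    def test_constant_fit_forecasts_constant(self, rng):
        X = rng.normal(size=(60, 2))
        fit = fit_ann(X, np.full(60, 3.0), AnnConfig(q_hidden=4, seed=5))
        assert np.allclose(forecast_ann(fit, rng.normal(size=(10, 2))), 3.0, atol=1e-6)

    def test_wrong_column_count_rejected(self, rng):
        fit = fit_ann(rng.normal(size=(50, 3)), rng.normal(size=50),
                      AnnConfig(q_hidden=4, seed=6))
        with pytest.raises(ValueError, match="column"):
            forecast_ann(fit, rng.normal(size=(5, 2)))

    def test_monotone_single_input_network_preserves_order(self):
        x = np.linspace(0, 1, 200)[:, None]
        y = 3.0 * x[:, 0] + 1.0
        fit = fit_ann(x, y, AnnConfig(q_hidden=12, seed=7))
        grid = np.linspace(0.05, 0.95, 30)[:, None]
        fc = forecast_ann(fit, grid)
        assert np.all(np.diff(fc) > -1e-6)

    def test_extrapolation_warns(self, rng):
        X = rng.uniform(0, 1, size=(80, 2))
        fit = fit_ann(X, rng.normal(size=80), AnnConfig(q_hidden=4, seed=8))
        with pytest.warns(UserWarning, match="extrapolat"):
            forecast_ann(fit, np.full((3, 2), 25.0))

    def test_minmax_scaling_makes_forecasts_affine_invariant(self, rng):
        X = rng.uniform(2, 8, size=(150, 3))
        y = X[:, 0] - X[:, 2] + rng.normal(0, 0.1, 150)
        fit_raw = fit_ann(X, y, AnnConfig(q_hidden=10, seed=11))
        fit_scaled = fit_ann(X * 100.0 - 7.0, y, AnnConfig(q_hidden=10, seed=11))
        new = rng.uniform(2.5, 7.5, size=(20, 3))
        assert np.allclose(
            forecast_ann(fit_raw, new), forecast_ann(fit_scaled, new * 100.0 - 7.0),
            atol=1e-8,
        )


class TestSelectHiddenNodes:
    def test_grid_of_one(self, rng):
        X = rng.normal(size=(100, 2))
        assert select_hidden_nodes(X, rng.normal(size=100), [6]) == 6

    def test_noisy_linear_target_prefers_small_capacity(self, rng):
        # weak linear signal in heavy noise: 50 units only overfit
        wins = 0
        for s in range(7):
            g = np.random.default_rng(40 + s)
            X = g.normal(size=(300, 3))
            y = 0.3 * X[:, 0] + g.normal(0, 3.0, 300)
            wins += select_hidden_nodes(X, y, [1, 50], AnnConfig(seed=s)) == 1
        assert wins >= 4

    def test_nonlinear_interaction_prefers_capacity(self, rng):
        wins = 0
        for s in range(7):
            g = np.random.default_rng(60 + s)
            X = g.uniform(-2, 2, size=(400, 2))
            y = np.sin(2 * X[:, 0]) * X[:, 1] + g.normal(0, 0.05, 400)
            wins += select_hidden_nodes(X, y, [1, 20], AnnConfig(seed=s)) == 20
        assert wins >= 4


class TestFeatureImportance:
    def test_percentages_sum_to_100(self, rng):
        X = rng.normal(size=(150, 6))
        y = rng.normal(size=150)
        fit = fit_ann(X, y, AnnConfig(q_hidden=10, seed=12))
        imp = feature_importance(fit, X, y)
        assert imp.sum() == pytest.approx(100.0)
        assert np.all(imp >= 0)

    def test_unused_input_gets_zero(self, rng):
        X = rng.normal(size=(100, 2))
        y = rng.normal(size=100)
        fit = fit_ann(X, y, AnnConfig(q_hidden=6, seed=13))
        fit.w_in[:, 1] = 0.0  # sever the second input
        imp = feature_importance(fit, X, y)
        assert imp[1] == pytest.approx(0.0, abs=1e-12)
        assert imp[0] == pytest.approx(100.0)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fit = fit_ann(X, y, AnnConfig(q_hidden=5, seed=14))

        def loss_grad_fd(i, eps=1e-6):
            acc = np.zeros(len(X))
            for t in range(len(X)):
                for sign in (1, -1):
                    Xp = X.copy()
                    Xp[t, i] += sign * eps
                    pred = forecast_ann(fit, Xp[t: t + 1])[0]
                    acc[t] += sign * (y[t] - pred) ** 2
            return acc / (2 * eps)

        analytic = feature_importance(fit, X, y)
        fd_raw = np.array([np.mean(np.abs(loss_grad_fd(i))) for i in range(4)])
        fd = 100.0 * fd_raw / fd_raw.sum()
        assert np.allclose(analytic, fd, rtol=1e-5)
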