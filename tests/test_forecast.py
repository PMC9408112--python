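import numpy as np
import pytest

from eldercare_coupling import (
    ForecastConfig,
    SyntheticConfig,
    coupling_table,
    fit_and_forecast,
    forecast_panel,
    generate_panel,
    make_windows,
)


class TestMakeWindows:
    @pytest.mark.parametrize("length,lag,expected", [(10, 3, 7), (4, 3, 1)])
    def test_window_counts(self, length, lag, expected):
        X, y = make_windows(np.arange(length, dtype=float), lag)
        assert X.shape == (expected, lag) and y.shape == (expected,)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_windows([1.0, 2.0, 3.0], 3)

    def test_no_look_ahead(self):
        """Each window holds only values strictly before its target; perturbing
        later values leaves earlier windows untouched."""
        series = np.arange(10, dtype=float)
        X, y = make_windows(series, 3)
        perturbed = series.copy()
        perturbed[-1] = 999.0
        Xp, yp = make_windows(perturbed, 3)
        np.testing.assert_array_equal(X[:-1], Xp[:-1])
        np.testing.assert_array_equal(y[:-1], yp[:-1])
        for t in range(len(y)):
            np.testing.assert_array_equal(X[t], series[t:t + 3])


class TestFitAndForecast:
    def test_constant_series_bypasses_network(self):
        res = fit_and_forecast(np.full(10, 5.0), ForecastConfig(seed=0))
        np.testing.assert_array_equal(res.forecasts, 5.0)
        assert res.loss == 0.0

    def test_deterministic_given_seed(self, rng):
        series = rng.uniform(10, 20, size=10)
        cfg = ForecastConfig(seed=11)
        r1 = fit_and_forecast(series, cfg)
        r2 = fit_and_forecast(series, cfg)
        np.testing.assert_allclose(r1.forecasts, r2.forecasts, atol=1e-9)
        np.testing.assert_allclose(r1.fitted, r2.fitted, atol=1e-9)

    def test_linear_series_one_step_within_ten_percent(self):
        series = 2.0 + 0.5 * np.arange(10)
        res = fit_and_forecast(series, ForecastConfig(seed=0))
        truth = 2.0 + 0.5 * 10
        assert abs(res.forecasts[0] - truth) / truth <= 0.10

    def test_nonnegative_forecasts(self):
        series = np.array([10.0, 8.0, 6.0, 4.0, 2.0, 1.0, 0.5, 0.3, 0.2, 0.1])
        res = fit_and_forecast(series, ForecastConfig(seed=1))
        assert (res.forecasts >= 0).all()

    def test_nonfinite_series_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_and_forecast([1.0, np.nan, 2.0, 3.0, 4.0, 5.0], ForecastConfig())

    @pytest.mark.parametrize("kind", ["linear", "exponential"])
    def test_beats_persistence_baseline(self, kind):
        """On noiseless trending series the network's one-step forecast should
        beat the last-value (persistence) forecast."""
        t = np.arange(10, dtype=float)
        series = (3.0 + 2.0 * t) if kind == "linear" else 5.0 * 1.15**t
        truth = (3.0 + 2.0 * 10) if kind == "linear" else 5.0 * 1.15**10
        res = fit_and_forecast(series, ForecastConfig(seed=0))
        network_err = abs(res.forecasts[0] - truth)
        persistence_err = abs(series[-1] - truth)
        assert network_err <= persistence_err


@pytest.fixture(scope="module")
def small_panel():
    cfg = SyntheticConfig(m_regions=4, years=(2010, 2015), seed=8)
    panel, _ = generate_panel(cfg)
    return panel


class TestForecastPanel:

    def test_shape_contract(self, small_panel):
        cfg = ForecastConfig(horizon=2, n_restarts=2, max_iter=100, seed=0)
        fpanel = forecast_panel(small_panel, cfg)
        assert fpanel.years == [2016, 2017]
        assert fpanel.regions == small_panel.regions
        assert len(fpanel.data) == 4 * 2 * 14

    def test_downstream_coupling_runs_on_forecast_panel(self, small_panel):
        cfg = ForecastConfig(horizon=2, n_restarts=2, max_iter=100, seed=0)
        fpanel = forecast_panel(small_panel, cfg)
        table = coupling_table(fpanel)
        assert set(table["year"]) == {2016, 2017}
        assert ((table["D"] >= 0) & (table["D"] <= 1)).all()

    def test_trendless_panel_forecast_stays_near_training_mean(self):
        """With no trend and modest noise, per-indicator forecast means should
        stay within 3 SD of the training-year means."""
        cfg = SyntheticConfig(m_regions=5, years=(2010, 2017), seed=21,
                              trend_rate=0.0, noise_cv=0.1)
        panel, _ = generate_panel(cfg)
        fpanel = forecast_panel(panel, ForecastConfig(horizon=2, n_restarts=2,
                                                      max_iter=100, seed=3))
        for ind in ["X1", "Y1"]:
            for region in panel.regions:
                train = panel.series(region, ind)
                fc = fpanel.series(region, ind)
                assert abs(fc.mean() - train.mean()) < 3 * train.std() + 1e-9
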