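"""Sliding-window neural forecasting of indicator series.

Each (region, indicator) yearly series is forecast independently with a
small one-hidden-layer feed-forward network in nonlinear input-output mode:
a window of the ``lag`` previous values predicts the next value, and
multi-step forecasts feed predictions back recursively. Series are min-max
scaled to [0, 1] before training and inverse-scaled (clipped at 0) after;
a constant series bypasses the network entirely.

Training is deterministic: full-batch L-BFGS from ``n_restarts`` seeded
initializations, keeping the fit with the lowest training loss. With ten
yearly observations and a lag of 3 there are only seven training windows,
so the default network is deliberately tiny (8 tanh units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .panel import IndicatorPanel


@dataclass(frozen=True)
class ForecastConfig:
    lag: int = 3
    hidden_units: int = 8
    activation: str = "tanh"
    max_iter: int = 300
    seed: int = 0
    horizon: int = 5
    n_restarts: int = 5

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ForecastResult:
    region: str
    indicator: str
    fitted: np.ndarray      # one-step in-sample predictions on training windows
    forecasts: np.ndarray   # horizon values, nonnegative
    loss: float


def make_windows(series, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged training pairs: (z_{t-lag}, ..., z_{t-1}) -> z_t."""
    z = np.asarray(series, dtype=float)
    if len(z) < lag + 1:
        raise ValueError(f"series of length {len(z)} too short for lag {lag}")
    X = np.stack([z[i:i + lag] for i in range(len(z) - lag)])
    y = z[lag:]
    return X, y


def fit_and_forecast(series, config: ForecastConfig, region: str = "",
                     indicator: str = "") -> ForecastResult:
    z = np.asarray(series, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("series contains non-finite values")
    if (z < 0).any():
        raise ValueError("indicator levels must be nonnegative")
    if len(z) < config.lag + 2:
        raise ValueError(f"need at least lag + 2 = {config.lag + 2} observations, got {len(z)}")

    lo, hi = z.min(), z.max()
    if hi == lo:  # constant series: the forecast is the constant
        n_fit = len(z) - config.lag
        return ForecastResult(region, indicator, np.full(n_fit, lo),
                              np.full(config.horizon, lo), 0.0)

    zs = (z - lo) / (hi - lo)
    X, y = make_windows(zs, config.lag)

    restart_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts) % (2**31 - 1)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for rs in restart_seeds:
            model = MLPRegressor(
                hidden_layer_sizes=(config.hidden_units,),
                activation=config.activation,
                solver="lbfgs",
                max_iter=config.max_iter,
                random_state=int(rs),
            )
            model.fit(X, y)
            if best is None or model.loss_ < best.loss_:
                best = model

    fitted = best.predict(X)
    window = list(zs[-config.lag:])
    preds = []
    for _ in range(config.horizon):
        nxt = float(best.predict(np.asarray(window[-config.lag:])[None, :])[0])
        preds.append(nxt)
        window.append(nxt)

    inv = lambda s: np.maximum(np.asarray(s) * (hi - lo) + lo, 0.0)
    return ForecastResult(region, indicator, inv(fitted), inv(preds), float(best.loss_))


def forecast_panel(panel: IndicatorPanel, config: ForecastConfig) -> IndicatorPanel:
    """Forecast every (region, indicator) series; returns a panel covering
    only the horizon years, ready for the downstream coupling pipeline."""
    horizon_years = [panel.years[-1] + k for k in range(1, config.horizon + 1)]
    keys = [(r, s.id) for r in panel.regions for s in panel.indicators]
    seeds = np.random.SeedSequence(config.seed).spawn(len(keys))

    rows = []
    for (region, ind), ss in zip(keys, seeds):
        series = panel.series(region, ind)
        sub_cfg = replace(config, seed=int(ss.generate_state(1)[0] % (2**31 - 1)))
        try:
            res = fit_and_forecast(series, sub_cfg, region=region, indicator=ind)
        except ValueError as err:
            raise ValueError(f"forecast failed for ({region}, {ind}): {err}") from err
        rows.extend(zip([region] * config.horizon, horizon_years,
                        [ind] * config.horizon, res.forecasts))

    df = pd.DataFrame(rows, columns=["region", "year", "indicator", "value"])
    return IndicatorPanel.from_long(df, panel.indicators)
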