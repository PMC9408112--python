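"""Coupling-coordination model of the supply and demand subsystems.

For one region-year with entropy-weighted composite scores T1 (supply) and
T2 (demand):

    C = 2 * sqrt(T1 * T2) / (T1 + T2)      coupling degree, 1 iff T1 == T2
    D = C * (alpha * T1 + beta * T2)       coupling coordination degree

with alpha = 0.4 and beta = 0.6 by default (demand weighted more heavily).
D is classified into ten 0.1-wide levels from extreme imbalance to excellent
balance, grouped into poor (< 0.4), medium ([0.4, 0.6)) and excellent
(>= 0.6) coordination. An optional ``sqrt_variant`` computes
D = sqrt(C * (alpha*T1 + beta*T2)), a form common elsewhere in the
coupling-coordination literature; it is off by default.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .entropy import WeightVector, compute_weights
from .panel import IndicatorPanel, SUBSYSTEMS
from .standardize import StandardizedMatrix, standardize_year

DEFAULT_ALPHA = 0.4
DEFAULT_BETA = 0.6

#: Ten-level classification, lower bin edge -> (level label, category).
LEVELS: list[tuple[float, str, str]] = [
    (0.0, "Extreme imbalance", "poor"),
    (0.1, "Serious imbalance", "poor"),
    (0.2, "Moderate imbalance", "poor"),
    (0.3, "Mild imbalance", "poor"),
    (0.4, "Close to imbalance", "medium"),
    (0.5, "Barely balance", "medium"),
    (0.6, "Primary balance", "excellent"),
    (0.7, "Moderate balance", "excellent"),
    (0.8, "Good balance", "excellent"),
    (0.9, "Excellent balance", "excellent"),
]


_FLOAT_SPILL = 1e-9


def _check_scores(t1, t2):
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    if (t1 < 0).any() or (t2 < 0).any():
        raise ValueError("subsystem scores must be nonnegative")
    if (t1 > 1 + _FLOAT_SPILL).any() or (t2 > 1 + _FLOAT_SPILL).any():
        raise ValueError("subsystem scores must lie in [0, 1]")
    # weighted averages of [0, 1] values can exceed 1 by rounding only
    return np.minimum(t1, 1.0), np.minimum(t2, 1.0)


def _check_alpha_beta(alpha, beta):
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError(f"alpha and beta must be nonnegative and sum to 1, got {alpha}, {beta}")


def coupling_degree(t1, t2):
    """C = 2*sqrt(T1*T2)/(T1+T2); 0 when both scores are 0. Scalar or array."""
    scalar = isinstance(t1, numbers.Number) and isinstance(t2, numbers.Number)
    t1, t2 = _check_scores(t1, t2)
    total = t1 + t2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(total > 0, 2.0 * np.sqrt(t1 * t2) / np.where(total > 0, total, 1.0), 0.0)
    c = np.minimum(c, 1.0)  # arithmetic-geometric mean bound, guard float spill
    return float(c) if scalar else c


def coordination_degree(t1, t2, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                        sqrt_variant: bool = False):
    """D = C * (alpha*T1 + beta*T2) (or its square-root variant)."""
    _check_alpha_beta(alpha, beta)
    scalar = isinstance(t1, numbers.Number) and isinstance(t2, numbers.Number)
    c = coupling_degree(t1, t2)
    t1, t2 = _check_scores(t1, t2)
    d = c * (alpha * t1 + beta * t2)
    if sqrt_variant:
        d = np.sqrt(d)
    return float(d) if scalar else d


def classify(d: float) -> tuple[str, str]:
    """Map a coordination degree to its (level label, category).

    Bins are half-open [a, a + 0.1) with the top bin closed at 1.0; category
    thresholds are poor < 0.4 <= medium < 0.6 <= excellent.
    """
    if not np.isfinite(d) or d < 0.0 or d > 1.0:
        raise ValueError(f"coordination degree must lie in [0, 1], got {d}")
    idx = min(int(d * 10), 9)
    _, level, category = LEVELS[idx]
    return level, category


def classify_series(d: pd.Series) -> pd.DataFrame:
    pairs = [classify(v) for v in d]
    return pd.DataFrame(pairs, columns=["level", "category"], index=d.index)


def composite_score(std: StandardizedMatrix, w: WeightVector, region: str) -> float:
    """T = sum_j W_j * z'_j for one region (Eqs: linear weighting)."""
    if (std.year, std.subsystem) != (w.year, w.subsystem):
        raise ValueError(
            f"standardized matrix ({std.year}, {std.subsystem}) does not match "
            f"weights ({w.year}, {w.subsystem})"
        )
    row = std.matrix.loc[region]
    return float(row @ w.weights.reindex(row.index))


def composite_scores(std: StandardizedMatrix, w: WeightVector) -> pd.Series:
    """Composite score for every region at once."""
    if (std.year, std.subsystem) != (w.year, w.subsystem):
        raise ValueError("standardized matrix and weights disagree on year/subsystem")
    return std.matrix @ w.weights.reindex(std.matrix.columns)


def coupling_table(
    panel: IndicatorPanel,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    sqrt_variant: bool = False,
    scope: str = "per_year",
) -> pd.DataFrame:
    """Full pipeline for a complete panel: standardize each year and
    subsystem, entropy-weight, score, couple, and classify.

    Returns a long table with one row per region-year and columns
    region, year, T_supply, T_demand, C, D, level, category.
    """
    _check_alpha_beta(alpha, beta)
    rows = []
    for year in panel.years:
        scores = {}
        for sub in SUBSYSTEMS:
            std = standardize_year(panel, year, sub, scope=scope)
            w = compute_weights(std)
            scores[sub] = composite_scores(std, w)
        t1, t2 = scores["supply"], scores["demand"]
        c = coupling_degree(t1.to_numpy(), t2.to_numpy())
        d = coordination_degree(t1.to_numpy(), t2.to_numpy(), alpha, beta, sqrt_variant)
        for i, region in enumerate(panel.regions):
            level, category = classify(d[i])
            rows.append((region, year, t1.iloc[i], t2.iloc[i], c[i], d[i], level, category))
    return pd.DataFrame(
        rows, columns=["region", "year", "T_supply", "T_demand", "C", "D", "level", "category"]
    )


def d_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Wide region x year matrix of coordination degrees with a period-mean
    column, mirroring the layout of published coupling tables."""
    wide = table.pivot(index="region", columns="year", values="D")
    wide["average"] = wide.mean(axis=1)
    return wide.reset_index()


def period_mean(d_values) -> float:
    """Arithmetic mean of a region's coordination degrees over a period."""
    arr = np.asarray(list(d_values), dtype=float)
    if arr.size == 0:
        raise ValueError("period mean of an empty series")
    return float(arr.mean())
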