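"""Min-max standardization of indicators across regions within a year.

Positive indicators map to (z - min) / (max - min), negative indicators to
(max - z) / (max - min), with min and max taken over the year's regions for
each indicator separately. A degenerate indicator (max == min carries no
cross-region information) is set to 0.5 everywhere and flagged, which drives
its entropy weight to zero downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import IndicatorPanel, PanelError, SUBSYSTEMS

DEGENERATE_FILL = 0.5

SCOPES = ("per_year", "pooled")


@dataclass
class StandardizedMatrix:
    """Region x indicator matrix of standardized values in [0, 1] for one
    year and one subsystem."""

    year: int
    subsystem: str
    matrix: pd.DataFrame
    degenerate_indicators: list[str]


def standardize_year(
    panel: IndicatorPanel,
    year: int,
    subsystem: str,
    scope: str = "per_year",
) -> StandardizedMatrix:
    """Standardize one year of one subsystem of a complete panel.

    ``scope="per_year"`` (default) takes min/max across regions within the
    year; ``"pooled"`` takes them across all region-years of the panel, for
    sensitivity analysis.
    """
    if subsystem not in SUBSYSTEMS:
        raise PanelError(f"subsystem must be one of {SUBSYSTEMS}")
    if scope not in SCOPES:
        raise PanelError(f"scope must be one of {SCOPES}")
    if len(panel.regions) < 2:
        raise PanelError("standardization needs at least 2 regions")
    mat = panel.wide(year, subsystem)

    if scope == "per_year":
        lo, hi = mat.min(axis=0), mat.max(axis=0)
    else:
        pooled = panel.data[panel.data["indicator"].isin(mat.columns)]
        grp = pooled.groupby("indicator")["value"]
        lo = grp.min().reindex(mat.columns)
        hi = grp.max().reindex(mat.columns)

    rng = hi - lo
    degenerate = list(mat.columns[rng.to_numpy() == 0.0])
    safe = rng.replace(0.0, np.nan)

    out = (mat - lo) / safe
    orient = {s.id: s.orientation for s in panel.indicators}
    for col in mat.columns:
        if orient[col] == "negative":
            out[col] = 1.0 - out[col]
    out[degenerate] = DEGENERATE_FILL
    # guard against 1e-17-scale float spill outside [0, 1]
    out = out.clip(lower=0.0, upper=1.0)
    return StandardizedMatrix(year=year, subsystem=subsystem, matrix=out, degenerate_indicators=degenerate)


def standardize_all(panel: IndicatorPanel, scope: str = "per_year") -> dict[tuple[int, str], StandardizedMatrix]:
    """Standardize every (year, subsystem) slice of a panel."""
    return {
        (year, sub): standardize_year(panel, year, sub, scope=scope)
        for year in panel.years
        for sub in SUBSYSTEMS
    }
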