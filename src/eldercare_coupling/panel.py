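"""Long-format indicator panels, region adjacency, and plain-text I/O.

The canonical interchange format is a long CSV with columns
``region,year,indicator,value``. A panel is *complete*: every
(region, year, indicator) cell must be present before any downstream
computation, mirroring the full region x year grid the coupling analysis
assumes. Values are nonnegative observed levels (persons, beds, m2, yuan).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

SUBSYSTEMS = ("supply", "demand")
ORIENTATIONS = ("positive", "negative")

PANEL_COLUMNS = ["region", "year", "indicator", "value"]


class PanelError(ValueError):
    """Base class for panel validation failures."""


class SchemaError(PanelError):
    """Unknown indicator id, bad column set, or malformed specification."""


class IncompletePanelError(PanelError):
    """Panel is missing cells; carries the missing (region, year, indicator) keys."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        preview = ", ".join(map(str, self.missing[:5]))
        more = "" if len(self.missing) <= 5 else f" (+{len(self.missing) - 5} more)"
        super().__init__(f"incomplete panel: missing cells {preview}{more}")


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator of the supply (X) or demand (Y) subsystem."""

    id: str
    subsystem: str
    orientation: str = "positive"
    label: str = ""
    unit: str = ""

    def __post_init__(self):
        if self.subsystem not in SUBSYSTEMS:
            raise SchemaError(f"subsystem must be one of {SUBSYSTEMS}, got {self.subsystem!r}")
        if self.orientation not in ORIENTATIONS:
            raise SchemaError(f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")


@dataclass
class IndicatorPanel:
    """Complete region x year x indicator panel of nonnegative levels.

    ``data`` is long-format with columns region, year, indicator, value,
    sorted by (region, year, indicator) for stable ordering.
    """

    regions: list[str]
    years: list[int]
    indicators: list[IndicatorSpec]
    data: pd.DataFrame = field(repr=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame, indicators: list[IndicatorSpec]) -> "IndicatorPanel":
        if list(df.columns) != PANEL_COLUMNS:
            raise SchemaError(f"expected columns {PANEL_COLUMNS}, got {list(df.columns)}")
        ids = [s.id for s in indicators]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate indicator ids in specification")
        unknown = set(df["indicator"]) - set(ids)
        if unknown:
            raise SchemaError(f"unknown indicator ids: {sorted(unknown)}")

        df = df.copy()
        df["region"] = df["region"].astype(str)
        df["year"] = df["year"].astype(int)
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = ~np.isfinite(values)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise PanelError(f"non-numeric or non-finite value at data row {row}")
        if (values < 0).any():
            row = int(df.index[values < 0][0]) + 2
            raise PanelError(f"negative value at data row {row}; indicator levels are nonnegative")
        df["value"] = values.astype(float)

        keys = list(zip(df["region"], df["year"], df["indicator"]))
        if len(set(keys)) != len(keys):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise PanelError(f"duplicate (region, year, indicator) keys: {sorted(dups)[:5]}")

        regions = sorted(df["region"].unique())
        years = sorted(df["year"].unique())
        expected = set(product(regions, years, ids))
        missing = expected - set(keys)
        if missing:
            raise IncompletePanelError(missing)

        df = df.sort_values(PANEL_COLUMNS[:3], kind="mergesort").reset_index(drop=True)
        return cls(regions=regions, years=years, indicators=list(indicators), data=df)

    @property
    def indicator_ids(self) -> list[str]:
        return [s.id for s in self.indicators]

    @property
    def indicator_map(self) -> dict[str, IndicatorSpec]:
        return {s.id: s for s in self.indicators}

    def subsystem_ids(self, subsystem: str) -> list[str]:
        if subsystem not in SUBSYSTEMS:
            raise SchemaError(f"subsystem must be one of {SUBSYSTEMS}")
        return [s.id for s in self.indicators if s.subsystem == subsystem]

    def wide(self, year: int, subsystem: str | None = None) -> pd.DataFrame:
        """Region x indicator value matrix for one year (optionally one subsystem)."""
        if year not in self.years:
            raise PanelError(f"year {year} not in panel ({self.years[0]}..{self.years[-1]})")
        sub = self.data[self.data["year"] == year]
        mat = sub.pivot(index="region", columns="indicator", values="value")
        cols = self.indicator_ids if subsystem is None else self.subsystem_ids(subsystem)
        return mat.reindex(index=self.regions, columns=cols)

    def series(self, region: str, indicator: str) -> np.ndarray:
        """Yearly value series for one (region, indicator), ordered by year."""
        sub = self.data[(self.data["region"] == region) & (self.data["indicator"] == indicator)]
        if sub.empty:
            raise PanelError(f"no series for ({region!r}, {indicator!r})")
        return sub.sort_values("year")["value"].to_numpy()

    def to_csv(self, path) -> None:
        write_results(self.data, path)


@dataclass
class AdjacencyMap:
    """Symmetric neighbor structure over named regions (no self-loops)."""

    regions: list[str]
    edges: set[frozenset]

    def __post_init__(self):
        known = set(self.regions)
        for e in self.edges:
            if len(e) != 2:
                raise PanelError(f"self-loop or malformed edge: {set(e)}")
            if not e <= known:
                raise PanelError(f"edge references unknown region: {sorted(e - known)}")

    def neighbors(self, region: str) -> list[str]:
        return sorted(other for e in self.edges if region in e for other in e if other != region)

    def degree(self, region: str) -> int:
        return sum(1 for e in self.edges if region in e)


def read_panel(path, spec: list[IndicatorSpec]) -> IndicatorPanel:
    """Read and validate a long-format panel CSV against an indicator specification."""
    df = pd.read_csv(path, dtype={"region": str})
    return IndicatorPanel.from_long(df, spec)


def read_adjacency(path, regions: list[str] | None = None) -> AdjacencyMap:
    """Read header-less neighbor pairs (comma- or whitespace-delimited, one per line)."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    edges = set()
    seen = set()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in re.split(r",|\t", line)] if ("," in line or "\t" in line) else line.split()
        parts = [p for p in parts if p]
        if len(parts) != 2:
            raise PanelError(f"line {lineno}: expected two region names, got {parts}")
        a, b = parts
        if a == b:
            raise PanelError(f"line {lineno}: self-loop {a!r}")
        seen.update(parts)
        edges.add(frozenset((a, b)))
    region_list = sorted(seen) if regions is None else list(regions)
    if regions is not None:
        unknown = seen - set(regions)
        if unknown:
            raise PanelError(f"adjacency references unknown regions: {sorted(unknown)}")
    return AdjacencyMap(regions=region_list, edges=edges)


def write_adjacency(adj: AdjacencyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(map(sorted, adj.edges)):
            fh.write(f"{e[0]},{e[1]}\n")


def write_results(table: pd.DataFrame, path, round_digits: int | None = None) -> None:
    """Write a result table as CSV.

    Full float precision by default so that read(write(x)) round-trips;
    ``round_digits=4`` matches the display rounding of published tables.
    """
    if table is None or len(table) == 0:
        raise PanelError("refusing to write an empty result table")
    fmt = None if round_digits is None else f"%.{round_digits}f"
    table.to_csv(path, index=False, float_format=fmt)
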