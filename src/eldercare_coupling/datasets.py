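"""Packaged reference data: the 14-indicator index system, the 31 mainland
China regions, a queen-contiguity adjacency fixture, and the published
reference coupling-coordination tables used for arithmetic cross-checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import AdjacencyMap, IndicatorSpec, read_adjacency

#: Supply (X1-X10) and demand (Y1-Y4) indicators of the elderly-care service
#: resource index system. All are "larger = more" levels, hence positive
#: orientation throughout.
DEFAULT_INDICATORS: list[IndicatorSpec] = [
    IndicatorSpec("X1", "supply", "positive", "Employees in pension institutions (year end)", "persons"),
    IndicatorSpec("X2", "supply", "positive", "Community service center employees (year end)", "persons"),
    IndicatorSpec("X3", "supply", "positive", "Number of pension institutions", "count"),
    IndicatorSpec("X4", "supply", "positive", "Number of beds for pension", "count"),
    IndicatorSpec("X5", "supply", "positive", "Building area of pension institutions", "m2"),
    IndicatorSpec("X6", "supply", "positive", "Number of community pension institutions", "count"),
    IndicatorSpec("X7", "supply", "positive", "Number of community day-care beds", "count"),
    IndicatorSpec("X8", "supply", "positive", "Elderly receiving the old-age allowance", "persons"),
    IndicatorSpec("X9", "supply", "positive", "Expenditure of welfare funds for the elderly", "million yuan"),
    IndicatorSpec("X10", "supply", "positive", "Subsidy level of ageing agencies", "yuan/person/year"),
    IndicatorSpec("Y1", "demand", "positive", "Population aged over 65", "persons"),
    IndicatorSpec("Y2", "demand", "positive", "Old-age dependency ratio", "%"),
    IndicatorSpec("Y3", "demand", "positive", "Per-capita disposable income", "yuan"),
    IndicatorSpec("Y4", "demand", "positive", "Elderly in pension institutions (year end)", "persons"),
]

#: The 31 mainland provincial-level regions, spelled as in the reference tables.
CHINA_REGIONS: list[str] = [
    "Beijing", "Tianjin", "Hebei", "Shanxi", "Inner Mongoria", "Liaoning",
    "Jilin", "Heilongjiang", "Shanghai", "Jiangsu", "Zhejiang", "Anhui",
    "Fujian", "Jiangxi", "Shandong", "Henan", "Hubei", "Hunan", "Guangdong",
    "Guangxi", "Hainan", "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Tibet",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
]

#: Published weight trajectory spot values for the building-area indicator X5:
#: weight 0.1302 in 2010 falling to 0.0946 in 2014, a 27.3% relative decline.
X5_WEIGHT_2010 = 0.1302
X5_WEIGHT_2014 = 0.0946


def _data_path(name: str):
    return resources.files("eldercare_coupling.data").joinpath(name)


def load_china_adjacency() -> AdjacencyMap:
    """Queen-contiguity neighbors of the 31 regions, with a Hainan-Guangdong
    bridge so no region is an island. One conventional choice among several."""
    with _data_path("china_region_adjacency.txt").open("r", encoding="utf-8") as fh:
        return read_adjacency(fh, regions=CHINA_REGIONS)


def load_reference_coupling(period: str = "observed") -> pd.DataFrame:
    """Published per-region coupling-coordination degrees D.

    ``period="observed"`` gives the 2010-2019 table, ``"forecast"`` the
    2020-2024 table. Columns: region, one column per year, and the printed
    row "average". Values are as printed, i.e. rounded to 4 decimals.
    """
    if period not in ("observed", "forecast"):
        raise ValueError("period must be 'observed' or 'forecast'")
    with _data_path(f"reference_coupling_{period}.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df.columns = [c if c in ("region", "average") else int(c) for c in df.columns]
    return df
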