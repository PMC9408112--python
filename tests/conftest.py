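import numpy as np
import pandas as pd
import pytest

from eldercare_coupling import IndicatorPanel, IndicatorSpec


def make_specs(n_supply=2, n_demand=2, negative=()):
    specs = []
    for k in range(n_supply):
        specs.append(IndicatorSpec(f"X{k + 1}", "supply",
                                   "negative" if f"X{k + 1}" in negative else "positive"))
    for k in range(n_demand):
        specs.append(IndicatorSpec(f"Y{k + 1}", "demand",
                                   "negative" if f"Y{k + 1}" in negative else "positive"))
    return specs


def make_panel(values, specs):
    """values: dict (region, year, indicator) -> value."""
    rows = [(r, y, i, v) for (r, y, i), v in values.items()]
    df = pd.DataFrame(rows, columns=["region", "year", "indicator", "value"])
    return IndicatorPanel.from_long(df, specs)


def random_panel(rng, regions=3, years=(2010, 2011), n_supply=2, n_demand=2):
    specs = make_specs(n_supply, n_demand)
    values = {
        (f"R{r}", y, s.id): float(rng.uniform(1.0, 100.0))
        for r in range(regions)
        for y in range(years[0], years[1] + 1)
        for s in specs
    }
    return make_panel(values, specs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_panel():
    """3 regions x 2 years x 2 indicators (one per subsystem)."""
    specs = make_specs(1, 1)
    values = {}
    for i, r in enumerate(["A", "B", "C"]):
        for y in (2010, 2011):
            values[(r, y, "X1")] = 2.0 + 4.0 * i + 0.1 * (y - 2010)
            values[(r, y, "Y1")] = 10.0 - 2.0 * i + 0.2 * (y - 2010)
    return make_panel(values, specs)
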