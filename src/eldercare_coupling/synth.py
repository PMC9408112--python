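"""Synthetic indicator panels with known ground truth.

The published analysis runs on yearbook levels that are not redistributable,
so every downstream stage is exercised on generated panels that mimic their
statistical shape: strictly positive levels spanning orders of magnitude
across regions, smooth multiplicative growth over years, and a tunable
correlation between a region's latent supply capacity u_p and latent demand
pressure v_p.

Generative model, on the log scale, for region p, year t, indicator j:

    log Z_pjt = log scale_j + s_p + loading_j * (u_p or v_p)
                + (t - t0) * log(1 + trend_rate) + eps_pjt

where s_p ~ N(0, region_scale_sd^2) is a shared region-size effect,
(u_p, v_p) is standard bivariate normal with correlation coupling_rho,
loading_j ~ U(0.4, 0.9), and eps is lognormal noise with coefficient of
variation noise_cv (mean 1 on the level scale). scale_j sets a realistic
magnitude per indicator unit. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AdjacencyMap, IndicatorPanel, IndicatorSpec

#: Rough level-scale anchors per default indicator (units per datasets.py).
_DEFAULT_SCALES = {
    "X1": 2e4, "X2": 5e4, "X3": 3e3, "X4": 2e5, "X5": 5e6,
    "X6": 1e4, "X7": 5e4, "X8": 1e6, "X9": 2e3, "X10": 1e3,
    "Y1": 5e6, "Y2": 14.0, "Y3": 2.5e4, "Y4": 1e5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for panel generation.

    Defaults emulate the analyzed setting: 31 regions observed yearly
    2010-2019, order-of-magnitude size differences between regions
    (region_scale_sd on the log scale), steady growth of care resources
    (trend_rate per year), moderate measurement noise, and a moderately
    coupled supply-demand relationship.
    """

    m_regions: int = 31
    years: tuple[int, int] = (2010, 2019)
    seed: int = 0
    region_scale_sd: float = 0.6
    trend_rate: float = 0.08
    noise_cv: float = 0.15
    coupling_rho: float = 0.6
    n_negative_indicators: int = 0

    def __post_init__(self):
        if self.m_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.years[1] - self.years[0] + 1 < 4:
            raise ValueError("need at least 4 years")
        if not self.noise_cv > 0:
            raise ValueError("noise_cv must be positive")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.region_scale_sd < 0:
            raise ValueError("region_scale_sd must be nonnegative")
        if not 0 <= self.n_negative_indicators <= 4:
            raise ValueError("n_negative_indicators flags demand indicators, 0..4")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticTruth:
    """Latent ground truth behind a generated panel."""

    u: pd.Series                # latent supply capacity per region
    v: pd.Series                # latent demand pressure per region
    region_size: pd.Series      # shared log-scale size effect s_p
    loadings: pd.Series         # per-indicator loading on u/v
    config: SyntheticConfig = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.u.index, "u": self.u.to_numpy(),
             "v": self.v.to_numpy(), "region_size": self.region_size.to_numpy()}
        )


def _default_indicators(n_negative: int) -> list[IndicatorSpec]:
    from .datasets import DEFAULT_INDICATORS

    specs = []
    demand_ids = [s.id for s in DEFAULT_INDICATORS if s.subsystem == "demand"]
    flagged = set(demand_ids[len(demand_ids) - n_negative:]) if n_negative else set()
    for s in DEFAULT_INDICATORS:
        orientation = "negative" if s.id in flagged else s.orientation
        specs.append(IndicatorSpec(s.id, s.subsystem, orientation, s.label, s.unit))
    return specs


def generate_panel(
    config: SyntheticConfig,
    indicators: list[IndicatorSpec] | None = None,
    loadings: dict[str, float] | None = None,
) -> tuple[IndicatorPanel, SyntheticTruth]:
    """Generate a complete panel plus its latent truth record.

    ``loadings`` optionally pins the latent loading of named indicators
    (e.g. to make one indicator dominate the cross-region variance);
    unnamed indicators keep their seeded U(0.4, 0.9) draw.
    """
    rng = np.random.default_rng(config.seed)
    specs = indicators if indicators is not None else _default_indicators(config.n_negative_indicators)
    regions = [f"R{i + 1:02d}" for i in range(config.m_regions)]
    years = config.year_list
    t0 = years[0]

    cov = np.array([[1.0, config.coupling_rho], [config.coupling_rho, 1.0]])
    uv = rng.multivariate_normal(np.zeros(2), cov, size=config.m_regions)
    u, v = uv[:, 0], uv[:, 1]
    size = rng.normal(0.0, config.region_scale_sd, size=config.m_regions)
    loading_arr = rng.uniform(0.4, 0.9, size=len(specs))
    if loadings:
        for j, spec in enumerate(specs):
            if spec.id in loadings:
                loading_arr[j] = loadings[spec.id]
    loadings = loading_arr

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    growth = np.log1p(config.trend_rate)

    rows = []
    for j, spec in enumerate(specs):
        latent = u if spec.subsystem == "supply" else v
        scale = _DEFAULT_SCALES.get(spec.id, 1e4)
        base = np.log(scale) + size + loadings[j] * latent  # per region
        for t in years:
            eps = rng.normal(-0.5 * sigma**2, sigma, size=config.m_regions)
            vals = np.exp(base + (t - t0) * growth + eps)
            rows.extend(zip(regions, [t] * config.m_regions, [spec.id] * config.m_regions, vals))

    df = pd.DataFrame(rows, columns=["region", "year", "indicator", "value"])
    panel = IndicatorPanel.from_long(df, specs)
    truth = SyntheticTruth(
        u=pd.Series(u, index=regions),
        v=pd.Series(v, index=regions),
        region_size=pd.Series(size, index=regions),
        loadings=pd.Series(loadings, index=[s.id for s in specs]),
        config=config,
    )
    return panel, truth


def generate_adjacency(m_regions: int, topology: str = "ring") -> AdjacencyMap:
    """Ring (every region exactly 2 neighbors) or rook-contiguity grid
    (m must be a perfect square) over synthetic region names."""
    regions = [f"R{i + 1:02d}" for i in range(m_regions)]
    edges = set()
    if topology == "ring":
        if m_regions < 3:
            raise ValueError("ring needs at least 3 regions")
        for i in range(m_regions):
            edges.add(frozenset((regions[i], regions[(i + 1) % m_regions])))
    elif topology == "grid":
        side = int(round(np.sqrt(m_regions)))
        if side * side != m_regions:
            raise ValueError(f"grid topology needs a perfect square, got {m_regions}")
        for r in range(side):
            for c in range(side):
                i = r * side + c
                if c + 1 < side:
                    edges.add(frozenset((regions[i], regions[i + 1])))
                if r + 1 < side:
                    edges.add(frozenset((regions[i], regions[i + side])))
    else:
        raise ValueError(f"unsupported topology {topology!r}; use 'ring' or 'grid'")
    return AdjacencyMap(regions=regions, edges=edges)
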