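"""Spatial weights and global Moran's I of the coordination degree.

    I = [ sum_pq W_pq (x_p - xbar)(x_q - xbar) / sum_pq W_pq ]
        * [ n / sum_p (x_p - xbar)^2 ]

Default weights are binary contiguity (W_pq = 1 iff p and q are neighbors):
the statistic already normalizes by the total weight, so row standardization
is optional. Inference is by random permutation of the values over regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AdjacencyMap

SCHEMES = ("binary", "row_standardized")


class IslandError(ValueError):
    """A region has no neighbors under the supplied adjacency."""


@dataclass
class SpatialWeights:
    regions: list[str]
    matrix: np.ndarray  # m x m, nonnegative, zero diagonal

    def __post_init__(self):
        m = len(self.regions)
        if self.matrix.shape != (m, m):
            raise ValueError(f"weight matrix must be {m}x{m}")
        if np.diag(self.matrix).any():
            raise ValueError("weight matrix must have a zero diagonal")
        if self.matrix.sum() <= 0:
            raise ValueError("total spatial weight must be positive")


@dataclass
class MoranResult:
    I: float
    n_used: int
    year: int | None = None
    permutation_p: float | None = None


def build_weights(adj: AdjacencyMap, scheme: str = "binary",
                  allow_islands: bool = False) -> SpatialWeights:
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    m = len(adj.regions)
    idx = {r: i for i, r in enumerate(adj.regions)}
    W = np.zeros((m, m))
    for e in adj.edges:
        a, b = tuple(e)
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = 1.0
    rowsums = W.sum(axis=1)
    islands = [r for r, s in zip(adj.regions, rowsums) if s == 0]
    if islands and not allow_islands:
        raise IslandError(f"island regions with no neighbors: {islands}")
    if scheme == "row_standardized":
        nz = rowsums > 0
        W[nz] = W[nz] / rowsums[nz, None]
    return SpatialWeights(regions=list(adj.regions), matrix=W)


def morans_i(x, w: SpatialWeights, year: int | None = None) -> MoranResult:
    x = np.asarray(x, dtype=float)
    n = len(w.regions)
    if x.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {x.shape}")
    if n < 3:
        raise ValueError("Moran's I needs at least 3 regions")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    W = w.matrix
    s0 = W.sum()
    i_val = float(z @ W @ z) / s0 * n / ss
    return MoranResult(I=i_val, n_used=n, year=year)


def permutation_test(x, w: SpatialWeights, n_perm: int = 999, seed: int = 0) -> float:
    """One-sided (greater) permutation p-value for Moran's I.

    p = (1 + #{I_perm >= I_obs}) / (n_perm + 1). Only the cross-product term
    varies under permutation (mean, variance and total weight are invariant),
    so each draw costs one matrix-vector product.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(x, dtype=float)
    obs = morans_i(x, w).I
    z = x - x.mean()
    W = w.matrix
    scale = len(z) / (float(z @ z) * W.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if float(zp @ W @ zp) * scale >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def moran_by_year(dmat: pd.DataFrame, w: SpatialWeights, n_perm: int | None = 999,
                  seed: int = 0) -> pd.DataFrame:
    """Moran's I of the coordination degree for every year column.

    ``dmat`` is a wide region x year table (as from ``coupling.d_matrix``,
    the "average" column is ignored). Rows are aligned to the weight
    matrix's region order.
    """
    dmat = dmat.set_index("region") if "region" in dmat.columns else dmat
    dmat = dmat.reindex(w.regions)
    if dmat.isna().any().any():
        raise ValueError("coordination table does not cover every region of the weight matrix")
    rows = []
    for col in dmat.columns:
        if col == "average":
            continue
        x = dmat[col].to_numpy()
        res = morans_i(x, w, year=int(col))
        p = permutation_test(x, w, n_perm=n_perm, seed=seed) if n_perm else None
        rows.append((int(col), res.I, res.n_used, p))
    return pd.DataFrame(rows, columns=["year", "moran_i", "n", "permutation_p"])
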