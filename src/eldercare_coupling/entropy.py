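"""Entropy weighting of standardized indicators.

For indicator j over n regions with standardized values z'_pj:

    S_pj = z'_pj / sum_p z'_pj          (proportion of region p in indicator j)
    K_j  = -(1/ln n) * sum_p S_pj ln S_pj   with 0 * ln 0 := 0
    D_j  = 1 - K_j                      (difference coefficient)
    W_j  = D_j / sum_j D_j              (normalized weight)

Less entropy (more cross-region dispersion) yields more weight. Weights are
computed per year and per subsystem. Indicators flagged degenerate by the
standardization step get weight exactly 0: their proportions are uniform, so
K_j = 1 analytically, and zeroing D_j avoids float residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standardize import StandardizedMatrix


class DegenerateMatrixError(ValueError):
    """Every indicator is degenerate — no discriminating information."""


@dataclass
class WeightVector:
    year: int
    subsystem: str
    weights: pd.Series        # W_j, sums to 1
    entropy: pd.Series        # K_j in [0, 1]
    difference: pd.Series     # D_j = 1 - K_j
    proportions: pd.DataFrame  # S_pj, regions x indicators

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "subsystem": self.subsystem,
                "indicator": self.weights.index,
                "weight": self.weights.to_numpy(),
                "entropy": self.entropy.to_numpy(),
                "difference_coefficient": self.difference.to_numpy(),
            }
        )


def compute_weights(std: StandardizedMatrix) -> WeightVector:
    mat = std.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("entropy weights need at least 2 regions")

    colsum = mat.sum(axis=0)
    # 0.5-fill for degenerate columns guarantees every column sum is positive
    assert (colsum > 0).all(), "zero column sum cannot occur under the degeneracy rule"
    S = mat / colsum

    with np.errstate(divide="ignore", invalid="ignore"):
        slns = np.where(S > 0, S * np.log(S), 0.0)
    K = pd.Series(-slns.sum(axis=0) / np.log(n), index=mat.columns).clip(0.0, 1.0)

    D = 1.0 - K
    D[std.degenerate_indicators] = 0.0
    total = D.sum()
    if total == 0.0:
        raise DegenerateMatrixError(
            f"no discriminating indicator in year {std.year} ({std.subsystem})"
        )
    W = D / total
    return WeightVector(
        year=std.year,
        subsystem=std.subsystem,
        weights=W,
        entropy=K,
        difference=D,
        proportions=S,
    )
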