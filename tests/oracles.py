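"""Independent brute-force transcriptions of the model equations.

Literal loop implementations used as oracles: min-max standardization,
entropy weighting, composite scoring, coupling/coordination, and Moran's I.
Deliberately slow and dumb; they share no code with the package.
"""

import math


def bf_standardize(matrix, orientations=None):
    """matrix: list of region-rows, each a list of indicator values."""
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    if orientations is None:
        orientations = ["positive"] * n_cols
    out = [[0.0] * n_cols for _ in range(n_rows)]
    for j in range(n_cols):
        col = [matrix[i][j] for i in range(n_rows)]
        lo, hi = min(col), max(col)
        for i in range(n_rows):
            if hi == lo:
                out[i][j] = 0.5
            elif orientations[j] == "positive":
                out[i][j] = (matrix[i][j] - lo) / (hi - lo)
            else:
                out[i][j] = (hi - matrix[i][j]) / (hi - lo)
    return out


def bf_weights(std):
    """Entropy weights from a standardized region x indicator matrix."""
    n = len(std)
    n_cols = len(std[0])
    K = []
    for j in range(n_cols):
        colsum = sum(std[i][j] for i in range(n))
        acc = 0.0
        for i in range(n):
            s = std[i][j] / colsum
            if s > 0:
                acc += s * math.log(s)
        K.append(-acc / math.log(n))
    D = [1.0 - k for k in K]
    # degenerate column (all equal): uniform proportions, K = 1 analytically
    for j in range(n_cols):
        col = [std[i][j] for i in range(n)]
        if max(col) == min(col):
            D[j] = 0.0
    total = sum(D)
    return [d / total for d in D]


def bf_composite(std_row, weights):
    return sum(w * z for w, z in zip(weights, std_row))


def bf_coupling(t1, t2):
    if t1 + t2 == 0:
        return 0.0
    return 2.0 * math.sqrt(t1 * t2) / (t1 + t2)


def bf_coordination(t1, t2, alpha=0.4, beta=0.6):
    return bf_coupling(t1, t2) * (alpha * t1 + beta * t2)


def bf_pipeline_d(supply, demand, alpha=0.4, beta=0.6):
    """Raw one-year region x indicator matrices -> per-region D values."""
    s_std = bf_standardize(supply)
    d_std = bf_standardize(demand)
    s_w = bf_weights(s_std)
    d_w = bf_weights(d_std)
    out = []
    for i in range(len(supply)):
        t1 = bf_composite(s_std[i], s_w)
        t2 = bf_composite(d_std[i], d_w)
        out.append(bf_coordination(t1, t2, alpha, beta))
    return out


def bf_morans_i(x, W):
    """Naive double-loop Moran's I."""
    n = len(x)
    xbar = sum(x) / n
    num = 0.0
    s0 = 0.0
    for p in range(n):
        for q in range(n):
            num += W[p][q] * (x[p] - xbar) * (x[q] - xbar)
            s0 += W[p][q]
    ss = sum((xi - xbar) ** 2 for xi in x)
    return (num / s0) * (n / ss)
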