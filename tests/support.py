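"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they check.
"""

import itertools

import numpy as np


def simplex_grid_min(Q, d, upper, step=1e-3):
    """Dense grid search for min x'Qx - d'x over the box-capped simplex.

    Enumerates every grid point with coordinates that are multiples of
    ``step`` summing to 1 (the last coordinate is the remainder), keeping
    only points inside the box.  Supports n in {1, 2, 3, 4}; the n = 4 case
    is chunked over the first coordinate to bound memory.
    Returns the minimal objective value found.
    """
    Q = np.asarray(Q, float)
    d = np.asarray(d, float).ravel()
    upper = np.asarray(upper, float).ravel()
    n = d.shape[0]
    m = int(round(1.0 / step))

    def _obj(cols):
        tot = np.zeros_like(cols[0])
        for a in range(n):
            tot -= d[a] * cols[a]
            for b in range(n):
                tot += Q[a, b] * cols[a] * cols[b]
        return tot

    if n == 1:
        return float(Q[0, 0] - d[0]) if upper[0] >= 1.0 else np.inf
    grid = np.arange(m + 1) * step
    best = np.inf
    if n == 2:
        x1 = grid[grid <= upper[0] + 1e-12]
        x2 = 1.0 - x1
        ok = (x2 >= -1e-12) & (x2 <= upper[1] + 1e-12)
        vals = _obj([x1[ok], x2[ok]])
        return float(vals.min())
    if n == 3:
        g1 = grid[grid <= upper[0] + 1e-12]
        g2 = grid[grid <= upper[1] + 1e-12]
        X1, X2 = np.meshgrid(g1, g2, indexing="ij")
        X3 = 1.0 - X1 - X2
        ok = (X3 >= -1e-12) & (X3 <= upper[2] + 1e-12)
        vals = _obj([X1[ok], X2[ok], X3[ok]])
        return float(vals.min())
    if n == 4:
        g2 = grid[grid <= upper[1] + 1e-12]
        g3 = grid[grid <= upper[2] + 1e-12]
        X2, X3 = np.meshgrid(g2, g3, indexing="ij")
        for x1 in grid[grid <= upper[0] + 1e-12]:
            X4 = 1.0 - x1 - X2 - X3
            ok = (X4 >= -1e-12) & (X4 <= upper[3] + 1e-12)
            if not ok.any():
                continue
            cols = [np.full(ok.sum(), x1), X2[ok], X3[ok], X4[ok]]
            v = _obj(cols).min()
            if v < best:
                best = float(v)
        return best
    raise ValueError("oracle supports n <= 4")


def wilcoxon_bruteforce(x, y):
    """Exact two-sided signed-rank p by literal enumeration of all 2^n signs."""
    from scipy.stats import rankdata

    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.shape[0]
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count_le = count_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count_le += w <= w_obs + 1e-9
        count_ge += w >= w_obs - 1e-9
    total = 2**n
    return min(1.0, 2.0 * min(count_le / total, count_ge / total))
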