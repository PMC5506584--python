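"""Independent brute-force oracles used by the acceptance script.

These deliberately avoid the package's vectorised code paths: explicit
per-series ranking loops for the concordance coefficient and
normal-equation regressions for the Granger F-statistic.
"""

from __future__ import annotations

import numpy as np


def kendall_bruteforce(series: np.ndarray) -> float:
    """Direct evaluation of Kendall's W from its definition."""
    m, t = series.shape
    ranks = np.empty((m, t))
    for i in range(m):
        order = np.argsort(series[i], kind="stable")
        rank = np.empty(t)
        rank[order] = np.arange(1, t + 1)
        for val in np.unique(series[i]):
            sel = series[i] == val
            rank[sel] = rank[sel].mean()
        ranks[i] = rank
    s = 0.0
    for tt in range(t):
        r_t = sum(ranks[i, tt] for i in range(m))
        s += (r_t - m * (t + 1) / 2.0) ** 2
    return 12.0 * s / (m * m * (t ** 3 - t))


def granger_oracle(x: np.ndarray, y: np.ndarray, p: int) -> float:
    """Two-regression least-squares Granger F via normal equations."""
    t = x.size
    t_eff = t - p

    def rss(cols):
        design = np.column_stack(cols)
        beta = np.linalg.solve(design.T @ design, design.T @ y[p:])
        resid = y[p:] - design @ beta
        return float(resid @ resid)

    ylags = [y[p - k:t - k] for k in range(1, p + 1)]
    xlags = [x[p - k:t - k] for k in range(1, p + 1)]
    ones = [np.ones(t_eff)]
    rss_r = rss(ones + ylags)
    rss_u = rss(ones + ylags + xlags)
    return ((rss_r - rss_u) / p) / (rss_u / (t_eff - 2 * p - 1))
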