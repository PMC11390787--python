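"""Independent brute-force oracles used to validate the statistics layer.

Each oracle implements its test from first principles (direct formulas,
risk-set enumeration, exhaustive table enumeration) without going through
scipy/lifelines/statsmodels, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2, hypergeom


def pearson_oracle(x, y) -> float:
    """Pearson r by the direct sum formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x**2).sum() - sx**2) * math.sqrt(n * (y**2).sum() - sy**2)
    return num / den


def logrank_oracle(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square by explicit risk-set enumeration."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    in_a = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d_t = int((events & (times == t)).sum())
        d_a = int((events & (times == t) & in_a).sum())
        e_a = d_t * n_a / n_t
        o_minus_e += d_a - e_a
        if n_t > 1:
            var += d_t * (n_a / n_t) * (1 - n_a / n_t) * (n_t - d_t) / (n_t - 1)
    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, df=1))


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by full enumeration of margin-preserving tables."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p_k = hypergeom.pmf(k, n, c1, r1)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up applied by hand."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def vif_oracle(design, j) -> float:
    """VIF of column j via an explicit auxiliary regression."""
    X = np.asarray(design, dtype=float)
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    return np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
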