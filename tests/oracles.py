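"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle implements the defining formula directly (enumeration,
numerical integration, closed form) without touching the library code
paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def bh_bruteforce(pvalues) -> np.ndarray:
    """Step-up BH from the definition: adj_(i) = min_{j>=i} m p_(j) / j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        candidates = []
        for rank2, idx2 in enumerate(order, start=1):
            if rank2 >= rank:
                candidates.append(m * p[idx2] / rank2)
        adj[idx] = min(1.0, min(candidates))
    return np.array(adj)


def t_sf_numeric(t: float, df: int) -> float:
    """Upper-tail Student-t probability by numerical integration."""

    def density(x):
        c = math.gamma((df + 1) / 2) / (
            math.sqrt(df * math.pi) * math.gamma(df / 2)
        )
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(density, t, np.inf)
    return val


def t_two_tailed_df2(t: float) -> float:
    """Closed-form two-tailed p for df=2: 1 - |t|/sqrt(2 + t^2)."""
    return 1.0 - abs(t) / math.sqrt(2.0 + t * t)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by summing the hypergeometric pmf from binomials."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


def genorm_m_bruteforce(log2_counts) -> dict:
    """geNorm M by explicit pairwise loops over a gene -> values mapping."""
    genes = list(log2_counts.keys())
    m = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            diffs = [a - b for a, b in zip(log2_counts[g], log2_counts[h])]
            mean = sum(diffs) / len(diffs)
            var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
            sds.append(math.sqrt(var))
        m[g] = sum(sds) / len(sds)
    return m


def pearson_bruteforce(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den
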