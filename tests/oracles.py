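"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are checking: Fisher exact p-values by direct
hypergeometric enumeration with integer combinatorics, and
Benjamini-Hochberg by the literal step-up definition.
"""

from math import comb

import numpy as np


def hypergeom_pmf(k: int, row1: int, col1: int, total: int) -> float:
    """P(X = k) for the 2x2 table margin (row1, col1, total)."""
    return comb(col1, k) * comb(total - col1, row1 - k) / comb(total, row1)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p of [[a, b], [c, d]] by
    enumerating the hypergeometric upper tail."""
    row1, col1, total = a + b, a + c, a + b + c + d
    k_max = min(row1, col1)
    return sum(hypergeom_pmf(k, row1, col1, total) for k in range(a, k_max + 1))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of probabilities of all tables with
    the same margins that are no more likely than the observed one."""
    row1, col1, total = a + b, a + c, a + b + c + d
    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    p_obs = hypergeom_pmf(a, row1, col1, total)
    tol = p_obs * (1 + 1e-7)
    return sum(p for k in range(k_min, k_max + 1)
               if (p := hypergeom_pmf(k, row1, col1, total)) <= tol)


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule:
    q_(i) = min_{j >= i} p_(j) * n / j on the sorted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def empirical_survival(times, eval_times) -> np.ndarray:
    """P(T > t) from fully observed event times."""
    times = np.asarray(times, dtype=float)
    return np.array([(times > t).mean() for t in eval_times])
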