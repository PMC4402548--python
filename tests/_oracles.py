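"""Independent oracles used across the test suite.

These are deliberately naive implementations — exhaustive enumeration for
the hypergeometric tail and a literal step-up loop for BH — kept separate
from the package so the checks stay dual-route.
"""

from itertools import combinations

import numpy as np


def enumerate_upper_tail(N: int, R: int, n: int, r: int) -> float:
    """P(overlap >= r) by enumerating every size-R subset of an N-universe
    whose first n elements are marked."""
    marked = set(range(n))
    hits = sum(1 for combo in combinations(range(N), R) if len(marked & set(combo)) >= r)
    total = sum(1 for _ in combinations(range(N), R))
    return hits / total


def overlap_distribution(N: int, R: int, n: int) -> dict:
    """overlap -> number of size-R subsets achieving it (full enumeration)."""
    counts: dict = {}
    for combo in combinations(range(N), R):
        k = sum(1 for x in combo if x < n)
        counts[k] = counts.get(k, 0) + 1
    return counts


def stepup_bh(p_values) -> np.ndarray:
    """Literal 1995 step-up definition: adjusted p_(k) = min over j >= k of
    p_(j) * m / j, capped at 1, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    for k in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(k, m)]
        adjusted_sorted[k] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
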