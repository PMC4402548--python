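"""Exact hypergeometric upper-tail test and Benjamini-Hochberg FDR control.

This is the statistical kernel shared by every enrichment strategy in the
package.  An over-representation analysis asks: drawing ``R`` elements
(the query) without replacement from a universe of ``N`` elements of which
``n`` are marked (the reference set), how likely is an overlap of at least
``r``?  The answer is the upper tail of the hypergeometric distribution:

    P(X >= r) = sum_{i=r}^{min(n, R)} C(n, i) C(N-n, R-i) / C(N, R)

All factorials are evaluated in log-gamma space and the tail is summed with
a max-shift (log-sum-exp), so universes in the tens of thousands of genes do
not overflow.  Multiple testing across pathways is controlled with the
Benjamini-Hochberg step-up procedure and pathways are selected at a strict
FDR threshold (``fdr < alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyCounts",
    "TestResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "select_significant",
    "SMALLEST_POSITIVE",
]

#: p-values that underflow to exactly 0 are clamped here so that log-scale
#: reporting never produces -inf.
SMALLEST_POSITIVE: float = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class ContingencyCounts:
    """The four counts of a single over-representation test.

    Attributes
    ----------
    N : universe size.
    R : query size (elements drawn).
    n : reference size (marked elements in the universe).
    r : overlap between query and reference.
    """

    N: int
    R: int
    n: int
    r: int

    def __post_init__(self) -> None:
        for name in ("N", "R", "n", "r"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.R > self.N:
            raise ValueError(f"R={self.R} exceeds universe N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds universe N={self.N}")
        if self.r > min(self.R, self.n):
            raise ValueError(
                f"r={self.r} exceeds min(R, n)={min(self.R, self.n)}"
            )
        if self.r < max(0, self.R + self.n - self.N):
            raise ValueError(
                f"r={self.r} below forced overlap "
                f"max(0, R+n-N)={max(0, self.R + self.n - self.N)}"
            )


@dataclass
class TestResult:
    """Counts plus raw p-value and (after correction) BH-adjusted FDR."""

    counts: ContingencyCounts
    p_value: float
    fdr: Optional[float] = None

    def with_fdr(self, fdr: float) -> "TestResult":
        return replace(self, fdr=float(fdr))


def _log_binom(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(a) + 1) - gammaln(np.asarray(b) + 1) - gammaln(
        np.asarray(a) - np.asarray(b) + 1
    )


def hypergeom_upper_tail(counts: ContingencyCounts) -> float:
    """P(overlap >= r) when drawing R of N elements, n of which are marked.

    Symmetric under swapping R and n; evaluated in log space.  A result that
    underflows to 0.0 is clamped to the smallest positive double.
    """
    N, R, n, r = counts.N, counts.R, counts.n, counts.r
    lo = max(0, R + n - N)
    if r <= lo:
        return 1.0
    i = np.arange(r, min(n, R) + 1)
    log_terms = _log_binom(n, i) + _log_binom(N - n, R - i) - _log_binom(N, R)
    p = float(np.exp(logsumexp(log_terms)))
    p = min(p, 1.0)
    return p if p > 0.0 else SMALLEST_POSITIVE


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending, multiply the k-th smallest by m/k, enforce monotone
    non-decrease with a cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = p[order] * m / ranks
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(stepped[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


def select_significant(table, alpha: float = 0.05):
    """Rows with ``fdr < alpha`` (strict), input order preserved.

    Accepts either a pandas DataFrame with an ``fdr`` column or any object
    exposing one through a ``rows`` attribute (an EnrichmentTable); the
    return type matches the input.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if hasattr(table, "rows"):
        sub = table.rows[table.rows["fdr"] < alpha].reset_index(drop=True)
        return replace(table, rows=sub)
    return table[table["fdr"] < alpha].reset_index(drop=True)
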