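"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: set-partition
enumeration for exact modularity maxima, truncated walk sums for
bipartivity, and exhaustive block search for rank windows.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def set_partitions(n: int) -> tuple[tuple[int, ...], ...]:
    """All partitions of {0..n-1} as canonical label tuples (Bell(n) many)."""
    if n == 1:
        return ((0,),)
    out = []
    for smaller in set_partitions(n - 1):
        k = max(smaller) + 1
        for label in range(k + 1):
            out.append(smaller + (label,))
    return tuple(out)


def exhaustive_max_modularity(adjacency: np.ndarray, gamma: float) -> float:
    """Exact maximum of binary/weighted modularity over all partitions."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    two_m = a.sum()
    strengths = a.sum(axis=1)
    best = -np.inf
    for labels in set_partitions(n):
        lab = np.asarray(labels)
        same = lab[:, None] == lab[None, :]
        internal = a[same].sum()
        s_tot = np.bincount(lab, weights=strengths)
        q = internal / two_m - gamma * np.sum((s_tot / two_m) ** 2)
        if q > best:
            best = q
    return float(best)


def walk_series_bipartivity(adjacency: np.ndarray, n_terms: int = 30) -> float:
    """Even/total closed-walk ratio from truncated power sums of A.

    beta = sum_k tr(A^{2k}) / (2k)!  /  sum_k tr(A^k) / k!   (k = 0..n_terms)
    """
    a = np.asarray(adjacency, dtype=float)
    power = np.eye(a.shape[0])
    total = 0.0
    even = 0.0
    factorial = 1.0
    for k in range(n_terms + 1):
        if k > 0:
            power = power @ a
            factorial *= k
        term = np.trace(power) / factorial
        total += term
        if k % 2 == 0:
            even += term
    return even / total


def brute_force_window(n_edges: int, s: float, wbar: float) -> tuple[int, int]:
    """Best contiguous rank block by direct enumeration over all placements."""
    length = int(np.floor(s * n_edges + 0.5))
    length = max(1, min(length, n_edges))
    best = None
    for lo in range(1, n_edges - length + 2):
        ranks = np.arange(lo, lo + length)
        mean_pct = ((ranks - 0.5) / n_edges).mean()
        err = abs(mean_pct - wbar)
        if best is None or err < best[0] - 1e-15:
            best = (err, lo)
    lo = best[1]
    return lo, lo + length - 1
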