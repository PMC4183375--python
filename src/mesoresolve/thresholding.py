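"""Soft, cumulative, and windowed thresholding of weighted networks.

Three complementary transforms probe structure at different connection
strengths:

* **soft thresholding** re-weights the (max-normalized) matrix elementwise,
  ``w -> w**r``; no edge is removed, but small ``r`` equalizes weights
  (approaching a hard threshold at zero) while large ``r`` lets the
  strongest edges dominate;
* **cumulative thresholding** binarizes by keeping edges above a single
  weight threshold tau;
* **windowed thresholding** binarizes by keeping a fixed-size contiguous
  band of edges by weight *rank*, characterized by the band's mean
  percentile weight (the "connection weight" W̄).  Fixing the retained
  fraction ``s`` holds connection density constant across the family of
  binary graphs, removing density as a confound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import BinaryGraph, WeightedNetwork, normalize_weights

__all__ = [
    "ThresholdWindow",
    "soft_threshold",
    "cumulative_threshold",
    "window_bounds",
    "windowed_threshold",
    "window_grid",
    "ranked_edges",
]


def round_half_away(x: float) -> int:
    """round() with half-away-from-zero ties, used for edge-count budgets."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ThresholdWindow:
    """Rank window retaining a fraction ``s`` of edges at mean percentile W̄.

    Percentile of the ascending weight rank ``i`` (1-based) is
    ``(i - 0.5) / M``; the feasible W̄ range is ``[s/2, 1 - s/2]``.
    """

    window_size: float
    mean_percentile: float

    def __post_init__(self) -> None:
        if not 0 < self.window_size <= 1:
            raise ValueError("window_size must lie in (0, 1]")
        lo, hi = self.window_size / 2, 1 - self.window_size / 2
        if not lo - 1e-12 <= self.mean_percentile <= hi + 1e-12:
            raise ValueError(
                f"mean percentile {self.mean_percentile} outside "
                f"feasible range [{lo}, {hi}] for s={self.window_size}"
            )


def soft_threshold(net: WeightedNetwork, r: float) -> WeightedNetwork:
    """Raise every normalized weight to the power ``r`` (r = 1: identity).

    The edge set is unchanged for any ``r > 0`` and the transform is
    monotone, so weight order is preserved.
    """
    if r <= 0:
        raise ValueError("soft-threshold exponent r must be positive")
    net = normalize_weights(net)
    if r == 1.0:
        return net
    return net.with_weights(np.power(net.weights, r))


def cumulative_threshold(net: WeightedNetwork, tau: float) -> BinaryGraph:
    """Binary support of edges with weight strictly above ``tau``."""
    if tau < 0:
        raise ValueError("threshold tau must be nonnegative")
    return BinaryGraph((net.weights > tau).astype(float), node_ids=net.node_ids)


def ranked_edges(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edges sorted ascending by weight; ties broken by stable (i, j) order.

    Returns ``(rows, cols)`` of the sorted upper-triangle edges, so each
    (s, W̄) pair maps to a unique edge set even with heavily tied weight
    distributions (hierarchical models have ties by construction).
    """
    i, j = np.triu_indices(matrix.shape[0], k=1)
    w = matrix[i, j]
    mask = w > 0
    i, j, w = i[mask], j[mask], w[mask]
    order = np.argsort(w, kind="stable")
    return i[order], j[order]


def window_bounds(n_edges: int, window: ThresholdWindow) -> tuple[int, int]:
    """1-based ascending-rank bounds (inclusive) of the retained block.

    The block has length ``round(s * M)`` (at least 1) and is placed so its
    mean rank percentile is closest to W̄, ties resolved toward lower ranks;
    placement is clipped to ``[1, M]``.
    """
    m = int(n_edges)
    if m < 1:
        raise ValueError("network has no edges to window")
    length = max(1, round_half_away(window.window_size * m))
    if length > m:
        length = m
    # mean percentile of the block starting at rank a (1-based):
    #   ((a + (a + length - 1)) / 2 - 0.5) / m
    target_mid = window.mean_percentile * m + 0.5
    a_star = target_mid - (length - 1) / 2
    a = int(math.floor(a_star))
    # candidates around the real-valued optimum; lower block wins ties
    best = None
    for cand in (a, a + 1):
        cand = min(max(cand, 1), m - length + 1)
        mid = cand + (length - 1) / 2
        err = abs((mid - 0.5) / m - window.mean_percentile)
        if best is None or err < best[0] - 1e-15:
            best = (err, cand)
    lo = best[1]
    return lo, lo + length - 1


def windowed_threshold(net: WeightedNetwork, window: ThresholdWindow,
                       weight_source: np.ndarray | None = None) -> BinaryGraph:
    """Binary graph of the edges whose ascending weight rank is in the window.

    ``weight_source`` optionally ranks edges by a different symmetric matrix
    (e.g., inter-node distance) while keeping the network's edge support.
    """
    matrix = net.weights if weight_source is None else np.asarray(weight_source, float)
    if matrix.shape != net.weights.shape:
        raise ValueError("weight source shape must match the network")
    if weight_source is not None:
        # rank only existing edges of the network, by the alternate weight
        matrix = np.where(net.weights > 0, matrix, 0.0)
    rows, cols = ranked_edges(matrix)
    lo, hi = window_bounds(len(rows), window)
    adj = np.zeros_like(net.weights)
    sel = slice(lo - 1, hi)
    adj[rows[sel], cols[sel]] = 1.0
    adj[cols[sel], rows[sel]] = 1.0
    return BinaryGraph(adj, node_ids=net.node_ids)


def window_grid(s: float, n_points: int) -> list[ThresholdWindow]:
    """Evenly spaced windows spanning the feasible W̄ range [s/2, 1 - s/2]."""
    if n_points < 2:
        raise ValueError("need at least two grid points")
    wbars = np.linspace(s / 2, 1 - s / 2, n_points)
    return [ThresholdWindow(s, float(w)) for w in wbars]
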