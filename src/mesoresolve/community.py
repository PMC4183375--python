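"""Modularity quality functions and Louvain-style greedy optimization.

The quality of a partition :math:`\\{g_i\\}` of a binary graph is

.. math::

    Q = \\frac{1}{2m} \\sum_{ij} \\Big[ B_{ij}
        - \\gamma \\frac{k_i k_j}{2m} \\Big] \\delta(g_i, g_j)

with the Newman–Girvan null model :math:`P_{ij} = k_i k_j / 2m`, and its
weighted generalization replaces ``B`` by the weight matrix, degrees by
strengths, and ``m`` by the total edge weight.  The structural resolution
parameter :math:`\\gamma` tunes community size: small values yield a few
large communities, large values fragment the network into singletons.

Optimization uses a locally greedy Louvain-style algorithm whose only
stochastic element is the random node visit order; because near-degenerate
optima are the rule rather than the exception, diagnostics are reported as
means and standard deviations over independent restarts (20 by default).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .network import BinaryGraph, WeightedNetwork

__all__ = [
    "Partition",
    "OptimizationResult",
    "modularity_binary",
    "modularity_weighted",
    "louvain_optimize",
    "resolution_sweep",
    "partition_statistics",
]


@dataclass(frozen=True)
class Partition:
    """Node-to-community assignment with derived size statistics."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D array")
        # canonicalize to 0..k-1 in order of first appearance
        _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
        order = np.argsort(np.argsort(first))
        canonical = np.ascontiguousarray(order[inverse])
        canonical.setflags(write=False)
        object.__setattr__(self, "labels", canonical)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    @property
    def n_singletons(self) -> int:
        return int(np.sum(self.sizes == 1))


def partition_statistics(partition: Partition) -> tuple[int, int, int, float]:
    """Return (n_communities, n_singletons, n_nonsingleton, mean nonsingleton size).

    The mean size of non-singleton communities is 0 by convention when every
    community is a singleton.
    """
    sizes = partition.sizes
    n_comm = sizes.size
    n_single = int(np.sum(sizes == 1))
    non = sizes[sizes > 1]
    mean_size = float(non.mean()) if non.size else 0.0
    return n_comm, n_single, int(non.size), mean_size


def _quality(matrix: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Shared Q evaluator: matrix is either 0/1 or weighted, zero diagonal."""
    two_m = float(matrix.sum())
    if two_m <= 0:
        raise ValueError("graph has no edges (m = 0)")
    strengths = matrix.sum(axis=1)
    k = int(labels.max()) + 1
    s_tot = np.zeros(k)
    np.add.at(s_tot, labels, strengths)
    # within-community weight, counting each ordered pair
    internal = float(matrix[labels[:, None] == labels[None, :]].sum())
    return internal / two_m - gamma * float(np.sum((s_tot / two_m) ** 2))


def modularity_binary(graph: BinaryGraph, partition: Partition,
                      gamma: float = 1.0) -> float:
    """Binary modularity Q under the Newman–Girvan null model."""
    if partition.n_nodes != graph.n_nodes:
        raise ValueError("partition size does not match graph")
    return _quality(graph.adjacency, partition.labels, gamma)


def modularity_weighted(net: WeightedNetwork, partition: Partition,
                        gamma: float = 1.0) -> float:
    """Weighted modularity Q^w; invariant under uniform weight rescaling."""
    if partition.n_nodes != net.n_nodes:
        raise ValueError("partition size does not match network")
    return _quality(net.weights, partition.labels, gamma)


# ---------------------------------------------------------------------------
# Louvain optimizer
# ---------------------------------------------------------------------------

def _adjacency_lists(matrix: np.ndarray):
    """Neighbor/weight lists plus per-node self-loop weights (aggregation)."""
    n = matrix.shape[0]
    neighbors: list[list[int]] = []
    weights: list[list[float]] = []
    for i in range(n):
        row = matrix[i]
        nz = np.flatnonzero(row)
        nz = nz[nz != i]
        neighbors.append(nz.tolist())
        weights.append(row[nz].tolist())
    loops = np.diag(matrix).astype(float)
    return neighbors, weights, loops


def _one_level(neighbors, weights, loops, strengths, two_m, gamma, rng):
    """Phase 1: local moves until no single move improves Q.

    Each visit moves the node to a community drawn uniformly at random among
    the strictly improving candidates (rather than deterministically to the
    best one); zero gains keep the node where it is, so the sweep
    terminates.  Random-improving selection lets independent restarts reach
    local optima that best-move dynamics provably cannot, at equal quality.
    Returns the community labels and whether any move was made.
    """
    n = len(neighbors)
    comm = list(range(n))
    s_tot = list(strengths)
    counts = [1] * n
    free: list[int] = []          # labels emptied by moves, reusable for splits
    inv_two_m = gamma / two_m
    order = list(range(n))
    rng.shuffle(order)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = comm[i]
            s_i = strengths[i]
            # links from i to each adjacent community (excluding self-loop)
            links: dict[int, float] = {}
            for j, w in zip(neighbors[i], weights[i]):
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + w
            s_tot[ci] -= s_i
            stay_gain = links.get(ci, 0.0) - inv_two_m * s_i * s_tot[ci]
            improving = [
                c for c, w_ic in links.items()
                if c != ci and w_ic - inv_two_m * s_i * s_tot[c]
                > stay_gain + 1e-12
            ]
            # splitting off into an empty community has gain 0
            if stay_gain < -1e-12 and counts[ci] > 1 and free:
                improving.append(free[-1])
            best_c = improving[rng.randrange(len(improving))] if improving else ci
            s_tot[best_c] += s_i
            if best_c != ci:
                comm[i] = best_c
                counts[ci] -= 1
                counts[best_c] += 1
                if counts[ci] == 0:
                    free.append(ci)
                if counts[best_c] == 1 and free and free[-1] == best_c:
                    free.pop()
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(neighbors, weights, loops, comm):
    """Phase 2: collapse communities into super-nodes, keeping self-loops."""
    labels = sorted(set(comm))
    remap = {c: idx for idx, c in enumerate(labels)}
    k = len(labels)
    new_loops = [0.0] * k
    new_w: list[dict[int, float]] = [dict() for _ in range(k)]
    n = len(neighbors)
    for i in range(n):
        ci = remap[comm[i]]
        new_loops[ci] += loops[i]
        for j, w in zip(neighbors[i], weights[i]):
            cj = remap[comm[j]]
            if cj == ci:
                new_loops[ci] += w  # both (i,j) and (j,i) visited: counts twice
            elif cj in new_w[ci]:
                new_w[ci][cj] += w
            else:
                new_w[ci][cj] = w
    agg_neighbors = [list(d.keys()) for d in new_w]
    agg_weights = [list(d.values()) for d in new_w]
    remap_arr = remap
    return agg_neighbors, agg_weights, new_loops, remap_arr, k


def _louvain_single(matrix: np.ndarray, gamma: float, rng) -> np.ndarray:
    n = matrix.shape[0]
    neighbors, weights, loops = _adjacency_lists(matrix)
    two_m = float(matrix.sum())
    node_comm = np.arange(n)
    while True:
        strengths = [sum(w) + loops[i] for i, w in enumerate(weights)]
        comm, moved = _one_level(neighbors, weights, loops, strengths,
                                 two_m, gamma, rng)
        if not moved:
            break
        neighbors, weights, loops, remap, k = _aggregate(
            neighbors, weights, loops, comm)
        node_comm = np.array([remap[comm[c]] for c in node_comm])
        if k == 1:
            break
    return node_comm


@dataclass
class OptimizationResult:
    """Restart-level results of modularity maximization.

    Carries every run's partition and quality, plus across-run means and
    standard deviations of the reported diagnostics (quality, community
    count, singleton count, non-singleton count).  ``best`` is the
    highest-quality run.
    """

    gamma: float
    mode: str
    runs: list[tuple[Partition, float]]
    seed: int | None = None
    _stats: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("at least one optimization run required")
        qs = np.array([q for _, q in self.runs])
        stats = np.array([partition_statistics(p) for p, _ in self.runs])
        self._stats = {
            "quality": qs,
            "n_communities": stats[:, 0],
            "n_singletons": stats[:, 1],
            "n_nonsingleton": stats[:, 2],
            "mean_nonsingleton_size": stats[:, 3],
        }

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def best(self) -> tuple[Partition, float]:
        idx = int(np.argmax(self._stats["quality"]))
        return self.runs[idx]

    def mean(self, diagnostic: str = "quality") -> float:
        return float(self._stats[diagnostic].mean())

    def sd(self, diagnostic: str = "quality") -> float:
        return float(self._stats[diagnostic].std(ddof=1)) if self.n_runs > 1 else 0.0

    @property
    def partitions(self) -> list[Partition]:
        return [p for p, _ in self.runs]

    def summary(self) -> str:
        lines = [
            "Modularity maximization",
            "=" * 47,
            f"mode: {self.mode}    gamma: {self.gamma:g}    runs: {self.n_runs}",
            f"{'diagnostic':<24}{'mean':>11}{'sd':>11}",
            "-" * 47,
        ]
        for key in ("quality", "n_communities", "n_singletons",
                    "n_nonsingleton", "mean_nonsingleton_size"):
            lines.append(f"{key:<24}{self.mean(key):>11.5g}{self.sd(key):>11.3g}")
        return "\n".join(lines)


def louvain_optimize(graph: BinaryGraph | WeightedNetwork,
                     gamma: float = 1.0,
                     n_runs: int = 20,
                     seed: int | None = None) -> OptimizationResult:
    """Maximize (binary or weighted) modularity with restart averaging.

    Each restart shuffles the node visit order, runs greedy local moves to a
    local optimum, aggregates communities into super-nodes, and repeats until
    no move improves Q.  The reported quality is recomputed from the final
    partition with the exact quality function, so optimizer bookkeeping can
    never drift from the definition.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if isinstance(graph, BinaryGraph):
        matrix, mode = graph.adjacency, "binary"
    else:
        matrix, mode = graph.weights, "weighted"
    master = random.Random(seed)
    runs = []
    for _ in range(n_runs):
        rng = random.Random(master.randrange(2**31))
        labels = _louvain_single(matrix, gamma, rng)
        part = Partition(labels)
        runs.append((part, _quality(matrix, part.labels, gamma)))
    return OptimizationResult(gamma=gamma, mode=mode, runs=runs, seed=seed)


def resolution_sweep(graph: BinaryGraph | WeightedNetwork,
                     gamma_grid,
                     n_runs: int = 20,
                     seed: int | None = None) -> list[OptimizationResult]:
    """Optimize at each resolution in an ascending gamma grid."""
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(np.diff(gamma_grid) <= 0):
        raise ValueError("gamma grid must be strictly ascending")
    master = random.Random(seed)
    return [
        louvain_optimize(graph, gamma=float(g), n_runs=n_runs,
                         seed=master.randrange(2**31))
        for g in gamma_grid
    ]


def singleton_gamma(graph: BinaryGraph | WeightedNetwork) -> float:
    """Smallest resolution above which no pairwise merge has positive gain.

    For gamma > max_ij 2m w_ij / (s_i s_j) every partition coarser than
    all-singletons lowers Q, so the optimum is total fragmentation.
    """
    matrix = graph.adjacency if isinstance(graph, BinaryGraph) else graph.weights
    s = matrix.sum(axis=1)
    two_m = float(matrix.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = two_m * matrix / np.outer(s, s)
    return float(np.nanmax(np.where(matrix > 0, ratio, -np.inf)))
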