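"""Weighted benchmark network generators and ensemble/fixture builders.

Four classic topologies, weighted so that weight *rank* encodes the
structural feature each model isolates:

* **ER** — Erdős–Rényi: a fixed number of edges placed uniformly at random,
  weights i.i.d. uniform on (0, 1].  No structure at any weight.
* **RL** — ring lattice: edges fill topological-distance shells outward from
  nearest neighbours, weights decreasing linearly with shell distance.
* **SW** — modular small world: fully connected elementary clusters plus
  random inter-cluster edges; intra-cluster weights occupy a high band,
  inter-cluster weights a disjoint low band.
* **FH** — fractal hierarchical: complete elementary groups (weight 1)
  joined pairwise level by level, inter-level edge density falling
  geometrically (factor ``sigma``) and weight halving per level.

These are benchmark nulls, not biological models; they emulate the density
regimes of anatomical (sparse, N ~ 1000) and functional (dense, N ~ 90)
connectivity matrices so that diagnostic response curves can be validated
in settings where the ground truth is known.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .network import SpatialEmbedding, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "EnsembleSpec",
    "generate_er",
    "generate_ring_lattice",
    "generate_small_world",
    "generate_fractal_hierarchical",
    "sample_ensemble",
    "generate_embedded_modular",
    "generate_two_group_ensembles",
]

#: default disjoint weight bands for the small-world model: intra-cluster
#: weights are drawn high, inter-cluster weights low, so rank order encodes
#: cluster membership
SW_INTRA_BAND = (0.6, 1.0)
SW_INTER_BAND = (0.0, 0.4)   # open at 0: weights drawn in (0, 0.4]


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one synthetic network draw."""

    model: str                      # {"er", "rl", "sw", "fh"}
    n_nodes: int
    n_edges: int
    cluster_size: int = 4           # SW elementary cluster / FH group size
    sigma: float = 2.0              # FH level-density decay
    intra_band: tuple[float, float] = SW_INTRA_BAND
    inter_band: tuple[float, float] = SW_INTER_BAND
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in {"er", "rl", "sw", "fh"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes")
        pairs = self.n_nodes * (self.n_nodes - 1) // 2
        if not 1 <= self.n_edges <= pairs:
            raise ValueError(f"n_edges must lie in [1, {pairs}]")
        if self.model in {"sw", "fh"} and not 2 <= self.cluster_size <= self.n_nodes:
            raise ValueError("cluster/group size must be in [2, n_nodes]")

    def generate(self):
        if self.model == "er":
            return generate_er(self.n_nodes, self.n_edges, seed=self.seed)
        if self.model == "rl":
            return generate_ring_lattice(self.n_nodes, self.n_edges, seed=self.seed)
        if self.model == "sw":
            net, _ = generate_small_world(
                self.n_nodes, self.n_edges, self.cluster_size, seed=self.seed,
                intra_band=self.intra_band, inter_band=self.inter_band)
            return net
        net, _ = generate_fractal_hierarchical(
            self.n_nodes, self.n_edges, self.cluster_size, seed=self.seed,
            sigma=self.sigma)
        return net


@dataclass(frozen=True)
class EnsembleSpec:
    """Gaussian edge-count ensemble around a model specification."""

    model_spec: ModelSpec
    edge_count_mean: float
    edge_count_sd: float
    size: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ensemble size must be >= 1")
        if self.edge_count_sd < 0:
            raise ValueError("edge-count SD must be nonnegative")


def _pair_index_to_edge(n: int, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map flat upper-triangle indices to (i, j) node pairs."""
    iu = np.triu_indices(n, k=1)
    return iu[0][idx], iu[1][idx]


def _fill(n: int, rows, cols, weights) -> np.ndarray:
    mat = np.zeros((n, n))
    mat[rows, cols] = weights
    mat[cols, rows] = weights
    return mat


def generate_er(n_nodes: int, n_edges: int,
                seed: int | None = None) -> WeightedNetwork:
    """Erdős–Rényi G(N, M) with i.i.d. uniform (0, 1] edge weights."""
    ModelSpec("er", n_nodes, n_edges)
    rng = np.random.default_rng(seed)
    pairs = n_nodes * (n_nodes - 1) // 2
    chosen = rng.choice(pairs, size=n_edges, replace=False)
    rows, cols = _pair_index_to_edge(n_nodes, chosen)
    weights = 1.0 - rng.random(n_edges)   # uniform on (0, 1]
    return WeightedNetwork(_fill(n_nodes, rows, cols, weights))


def generate_ring_lattice(n_nodes: int, n_edges: int,
                          seed: int | None = None) -> WeightedNetwork:
    """Ring lattice filled shell by shell, weights linear in shell distance.

    Edges at topological distance 1 are placed first (in increasing start
    index), then distance 2, and so on until the edge budget is spent.  With
    ``d_used`` the farthest shell touched, an edge at distance ``d`` gets
    weight ``1 - (d - 1) / d_used``: nearest neighbours weigh 1 and the
    farthest used shell keeps a strictly positive weight ``1 / d_used``.
    The ``seed`` argument is accepted for interface symmetry; the model is
    deterministic.
    """
    ModelSpec("rl", n_nodes, n_edges)
    if n_edges < n_nodes:
        logger.warning(
            "ring lattice with n_edges=%d < n_nodes=%d leaves the ring "
            "incomplete", n_edges, n_nodes)
    edges: list[tuple[int, int, int]] = []   # (i, j, shell)
    d = 0
    while len(edges) < n_edges:
        d += 1
        if d > n_nodes // 2:
            raise ValueError("edge budget exceeds ring-lattice capacity")
        n_in_shell = n_nodes if (2 * d != n_nodes) else n_nodes // 2
        for i in range(n_in_shell):
            if len(edges) == n_edges:
                break
            j = (i + d) % n_nodes
            edges.append((min(i, j), max(i, j), d))
    d_used = max(e[2] for e in edges)
    rows = np.array([e[0] for e in edges])
    cols = np.array([e[1] for e in edges])
    weights = np.array([1.0 - (e[2] - 1) / d_used for e in edges])
    return WeightedNetwork(_fill(n_nodes, rows, cols, weights))


def _base_count(n_nodes: int, group: int) -> int:
    """Smallest 2**j * group >= n_nodes (the dyadic construction size)."""
    base = group
    while base < n_nodes:
        base *= 2
    return base


def _delete_surplus(base: int, n_nodes: int, rng) -> np.ndarray:
    """Indices of the nodes kept after random surplus deletion."""
    keep = rng.choice(base, size=n_nodes, replace=False)
    keep.sort()
    return keep


def generate_small_world(n_nodes: int, n_edges: int, cluster_size: int,
                         seed: int | None = None,
                         intra_band: tuple[float, float] = SW_INTRA_BAND,
                         inter_band: tuple[float, float] = SW_INTER_BAND,
                         ) -> tuple[WeightedNetwork, np.ndarray]:
    """Modular small-world network with disjoint intra/inter weight bands.

    Built on the smallest dyadic node count ``2**j * cluster_size >=
    n_nodes`` from consecutive fully connected clusters, then surplus nodes
    are deleted at random with their edges.  The remaining edge budget is
    placed uniformly at random between clusters.  Intra-cluster weights are
    uniform on ``intra_band``, inter-cluster weights uniform on
    ``(inter_band[0], inter_band[1]]``; with the default disjoint bands the
    weight rank order exactly encodes cluster membership.

    Returns the network together with the ground-truth cluster labels.
    """
    ModelSpec("sw", n_nodes, n_edges, cluster_size=cluster_size)
    rng = np.random.default_rng(seed)
    base = _base_count(n_nodes, cluster_size)
    keep = (_delete_surplus(base, n_nodes, rng) if base > n_nodes
            else np.arange(base))
    labels_full = np.repeat(np.arange(base // cluster_size), cluster_size)
    labels = labels_full[keep]

    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n_nodes, k=1)
    intra_mask = same[iu]
    intra_idx = np.flatnonzero(intra_mask)
    inter_idx = np.flatnonzero(~intra_mask)

    if n_edges < intra_idx.size:
        logger.warning(
            "edge budget %d below the %d intra-cluster edges; subsampling "
            "intra edges uniformly", n_edges, intra_idx.size)
        intra_idx = rng.choice(intra_idx, size=n_edges, replace=False)
        chosen_inter = np.empty(0, dtype=int)
    else:
        n_inter = n_edges - intra_idx.size
        chosen_inter = rng.choice(inter_idx, size=n_inter, replace=False)

    rows_a, cols_a = _pair_index_to_edge(n_nodes, intra_idx)
    rows_b, cols_b = _pair_index_to_edge(n_nodes, chosen_inter)
    lo, hi = intra_band
    w_intra = rng.uniform(lo, hi, size=intra_idx.size)
    lo, hi = inter_band
    w_inter = hi - rng.random(chosen_inter.size) * (hi - lo)  # (lo, hi]
    mat = _fill(n_nodes, np.concatenate([rows_a, rows_b]),
                np.concatenate([cols_a, cols_b]),
                np.concatenate([w_intra, w_inter]))
    return WeightedNetwork(mat), labels


def fh_level_structure(n_nodes: int, group_size: int) -> tuple[int, int]:
    """(base node count, number of hierarchy levels) of the FH construction."""
    base = _base_count(n_nodes, group_size)
    levels = int(round(math.log2(base // group_size))) + 1
    return base, levels


def fh_max_edges(n_nodes: int, group_size: int, sigma: float = 2.0) -> float:
    """Largest expected edge budget feasible for the FH model (p_2 = 1)."""
    base, levels = fh_level_structure(n_nodes, group_size)
    survival = (n_nodes / base) * ((n_nodes - 1) / (base - 1)) if base > n_nodes else 1.0
    intra = (base // group_size) * group_size * (group_size - 1) // 2
    total = float(intra)
    for level in range(2, levels + 1):
        pairs = group_size**2 * 2 ** (int(math.log2(base // group_size)) + level - 3)
        total += min(1.0, sigma ** (2 - level)) * pairs
    return total * survival


def generate_fractal_hierarchical(n_nodes: int, n_edges: int, group_size: int,
                                  seed: int | None = None,
                                  sigma: float = 2.0,
                                  ) -> tuple[WeightedNetwork, dict]:
    """Fractal hierarchical network with geometric weight ladder.

    On the dyadic base count ``2**h * group_size >= n_nodes``: level-1
    elementary groups are complete with weight 1; at each level ``l >= 2``
    sibling modules from level ``l - 1`` are joined by edges placed
    independently with probability ``p_l = p_2 * sigma**(2 - l)`` and weight
    ``2**(1 - l)``.  ``p_2`` is solved so the *expected* final edge count
    (after random surplus-node deletion) matches ``n_edges``; the realized
    count is stochastic.  With the default ``sigma = 2`` the density halves
    per level while eligible pair counts double, so each hierarchy level
    contributes roughly the same number of edges.

    Returns the network and a truth dict with per-level module labels,
    ``p2``, ``sigma``, and ``n_levels``.
    """
    ModelSpec("fh", n_nodes, n_edges, cluster_size=group_size, sigma=sigma)
    if sigma <= 1:
        raise ValueError("sigma must exceed 1 (density must decay per level)")
    rng = np.random.default_rng(seed)
    base, levels = fh_level_structure(n_nodes, group_size)
    h = levels - 1
    survival = (n_nodes / base) * ((n_nodes - 1) / (base - 1)) if base > n_nodes else 1.0

    intra = (base // group_size) * group_size * (group_size - 1) // 2
    pair_counts = {
        level: group_size**2 * 2 ** (h + level - 3) for level in range(2, levels + 1)
    }
    denom = sum(sigma ** (2 - level) * pair_counts[level]
                for level in range(2, levels + 1))
    target_base_edges = n_edges / survival
    if levels == 1:
        p2 = 0.0
        if abs(target_base_edges - intra) > 0.5:
            raise ValueError("single-level hierarchy fixes the edge count")
    else:
        p2 = (target_base_edges - intra) / denom
    if p2 < 0:
        raise ValueError(
            f"edge budget {n_edges} below the {intra * survival:.0f} expected "
            "elementary-group edges")
    if p2 > 1:
        raise ValueError(
            f"infeasible density: n_edges={n_edges} requires p_2={p2:.3f} > 1; "
            f"maximal feasible expected edge count is "
            f"{fh_max_edges(n_nodes, group_size, sigma):.0f}")

    group1 = np.repeat(np.arange(base // group_size), group_size)
    mat = np.zeros((base, base))
    for g in range(base // group_size):
        idx = np.flatnonzero(group1 == g)
        mat[np.ix_(idx, idx)] = 1.0

    level_labels = {1: group1}
    labels = group1
    for level in range(2, levels + 1):
        labels = labels // 2
        level_labels[level] = labels
        p_l = p2 * sigma ** (2 - level)
        prev = level_labels[level - 1]
        w_l = 2.0 ** (1 - level)
        for module in range(int(labels.max()) + 1):
            children = np.unique(prev[labels == module])
            a = np.flatnonzero(prev == children[0])
            b = np.flatnonzero(prev == children[1])
            mask = rng.random((a.size, b.size)) < p_l
            sub = np.zeros((a.size, b.size))
            sub[mask] = w_l
            mat[np.ix_(a, b)] = sub
            mat[np.ix_(b, a)] = sub.T
    np.fill_diagonal(mat, 0.0)

    keep = (_delete_surplus(base, n_nodes, rng) if base > n_nodes
            else np.arange(base))
    mat = mat[np.ix_(keep, keep)]
    truth = {
        "levels": {lvl: lab[keep] for lvl, lab in level_labels.items()},
        "n_levels": levels,
        "p2": p2,
        "sigma": sigma,
    }
    return WeightedNetwork(mat), truth


def sample_ensemble(spec: EnsembleSpec) -> list[WeightedNetwork]:
    """Draw an ensemble whose edge counts are Gaussian around the target.

    Per realization the edge count is drawn from
    ``Normal(edge_count_mean, edge_count_sd)``, rounded, and clipped to the
    valid range ``[n_nodes - 1, pairs]``; realization seeds are spawned
    deterministically from the master seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.model_spec.n_nodes
    pairs = n * (n - 1) // 2
    nets = []
    for _ in range(spec.size):
        count = int(round(rng.normal(spec.edge_count_mean, spec.edge_count_sd)))
        count = int(np.clip(count, n - 1, pairs))
        child_seed = int(rng.integers(2**31))
        ms = ModelSpec(
            spec.model_spec.model, n, count,
            cluster_size=spec.model_spec.cluster_size,
            sigma=spec.model_spec.sigma,
            intra_band=spec.model_spec.intra_band,
            inter_band=spec.model_spec.inter_band,
            seed=child_seed,
        )
        nets.append(ms.generate())
    return nets


def generate_embedded_modular(n_nodes: int, n_modules: int,
                              seed: int | None = None,
                              cloud_radius: float = 1.0,
                              centroid_distance: float = 20.0,
                              ) -> tuple[WeightedNetwork, SpatialEmbedding]:
    """Spatially embedded modular network for radius/laterality analyses.

    A small-world-style modular network whose modules occupy disjoint
    Gaussian coordinate clouds (cloud SD small relative to the
    inter-centroid spacing) placed on a ring in the x–y plane, with modules
    assigned alternately to the two category labels.
    """
    if n_modules < 2:
        raise ValueError("need at least two modules")
    if n_nodes % n_modules:
        raise ValueError("n_nodes must be divisible by n_modules")
    cluster = n_nodes // n_modules
    rng = np.random.default_rng(seed)
    intra = n_modules * cluster * (cluster - 1) // 2
    n_edges = intra + max(n_modules, intra // 4)   # sparse inter-module links
    net, labels = generate_small_world(
        n_nodes, n_edges, cluster, seed=int(rng.integers(2**31)))
    angles = 2 * np.pi * np.arange(n_modules) / n_modules
    centroids = centroid_distance * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(n_modules)])
    coords = centroids[labels] + rng.normal(0, cloud_radius, size=(n_nodes, 3))
    categories = labels % 2
    return net, SpatialEmbedding(coords, categories=categories)


def generate_two_group_ensembles(n_per_group: int, effect: float = 0.0,
                                 seed: int | None = None,
                                 n_nodes: int = 32, n_edges: int = 150,
                                 cluster_size: int = 8,
                                 ) -> tuple[list[WeightedNetwork], list[WeightedNetwork]]:
    """Two SW ensembles differing only by an intra-band weight shift.

    Group A uses the baseline bands; group B's intra-cluster band is shifted
    upward by ``effect``.  At ``effect = 0`` the groups are exchangeable, the
    null case for permutation-test calibration; a large effect raises group
    B's weighted modularity.
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    rng = np.random.default_rng(seed)
    lo, hi = SW_INTRA_BAND

    def draw(band):
        net, _ = generate_small_world(
            n_nodes, n_edges, cluster_size, seed=int(rng.integers(2**31)),
            intra_band=band, inter_band=SW_INTER_BAND)
        return net

    group_a = [draw((lo, hi)) for _ in range(n_per_group)]
    group_b = [draw((lo + effect, hi + effect)) for _ in range(n_per_group)]
    return group_a, group_b
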