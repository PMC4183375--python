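"""Mesoscale diagnostics: bipartivity, community laterality, community radius.

Bipartivity quantifies the extent to which a graph splits into two groups
with connections *between* but not *within* them — in that sense an
anti-community structure.  It is measured as the fraction of the subgraph
centrality contributed by closed walks of even length, computable from the
adjacency spectrum as

.. math::

    \\beta = \\frac{\\sum_j \\cosh \\lambda_j}{\\sum_j e^{\\lambda_j}},

which equals 1 exactly for bipartite graphs (symmetric spectrum) and
approaches 1/2 for complete graphs.

Laterality and radius describe how detected communities relate to a spatial
embedding: laterality measures confinement to one of two node categories
(e.g. cerebral hemispheres), radius measures the physical extent of a
community's node cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .community import Partition
from .network import BinaryGraph, SpatialEmbedding

logger = logging.getLogger(__name__)

__all__ = [
    "bipartivity",
    "spectral_bipartition",
    "community_laterality",
    "community_radius",
    "LateralityResult",
    "RadiusResult",
]


def bipartivity(graph: BinaryGraph) -> float:
    """Estrada–Rodríguez-Velázquez spectral bipartivity ``beta`` in [1/2, 1].

    Evaluated with the spectrum shifted by its maximum so that the
    exponentials cannot overflow on dense graphs.
    """
    lam = np.linalg.eigvalsh(graph.adjacency)
    shift = lam.max()
    pos = np.exp(lam - shift).sum()
    neg = np.exp(-lam - shift).sum()
    # cosh sum = (pos + neg)/2 after common rescaling by exp(-shift)
    return float(0.5 * (pos + neg) / pos)


def spectral_bipartition(graph: BinaryGraph, gamma: float = 1.0):
    """Two-group split from the lowest eigenvector of the modularity matrix.

    The modularity matrix ``B = A - gamma * k k^T / 2m`` has its most
    negative eigenvalue associated with bipartite-like structure (just as
    its top eigenvalues encode community structure).  Nodes are grouped by
    the sign of the corresponding eigenvector (zeros to group one), and the
    fraction of edges crossing the two groups is reported.

    Returns
    -------
    (group_one, group_two, crossing_fraction)
        Node-index arrays and the crossing edge fraction.
    """
    a = graph.adjacency
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    k = a.sum(axis=1)
    b_mod = a - gamma * np.outer(k, k) / two_m
    eigvals, eigvecs = eigh(b_mod)
    if eigvals.size > 1 and abs(eigvals[0] - eigvals[1]) < 1e-12 * max(
            1.0, abs(eigvals[0])):
        logger.warning(
            "degenerate smallest modularity-matrix eigenvalue; "
            "using the first eigenvector"
        )
    vec = eigvecs[:, 0]
    # canonical sign: make the first nonzero entry nonnegative so the
    # (unordered) pair of groups is deterministic
    nz = np.flatnonzero(vec)
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    group_one = np.flatnonzero(vec >= 0)
    group_two = np.flatnonzero(vec < 0)
    side = vec >= 0
    crossing = a[np.ix_(side, ~side)].sum()
    return group_one, group_two, float(crossing / (two_m / 2.0))


@dataclass(frozen=True)
class LateralityResult:
    """Null-corrected partition laterality with per-community detail."""

    per_community: np.ndarray     # Lambda_c in [0, 1]
    uncorrected: float            # (1/N) sum_c N_c Lambda_c
    null_expectation: float       # mean over label randomizations
    null_se: float                # Monte-Carlo standard error
    n_randomizations: int

    @property
    def corrected(self) -> float:
        """Partition laterality Λ = weighted mean − null expectation."""
        return self.uncorrected - self.null_expectation


def _weighted_laterality(labels: np.ndarray, cats: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-community |N_L - N_R| / N_c and the size-weighted partition mean."""
    sizes = np.bincount(labels).astype(float)
    ones = np.bincount(labels, weights=cats).astype(float)
    lam_c = np.abs(sizes - 2.0 * ones) / sizes
    return lam_c, float((sizes * lam_c).sum() / labels.size)


def community_laterality(partition: Partition, embedding: SpatialEmbedding,
                         n_random: int = 1000,
                         seed: int | None = None) -> LateralityResult:
    """Size-weighted community laterality, corrected by a label-shuffle null.

    Each community's laterality is ``|N_L,c - N_R,c| / N_c``; the partition
    value weights communities by size.  Because singletons are fully
    lateralized by definition, the raw value is biased upward for fragmented
    partitions; the expectation under random category reassignment (keeping
    the total count per category fixed — i.e. permuting the label vector) is
    subtracted, and its Monte-Carlo standard error reported.
    """
    if not embedding.has_categories:
        raise ValueError("laterality requires binary category labels")
    if embedding.n_nodes != partition.n_nodes:
        raise ValueError("embedding size does not match partition")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    cats = embedding.categories.astype(float)
    labels = partition.labels
    per_comm, observed = _weighted_laterality(labels, cats)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for t in range(n_random):
        null[t] = _weighted_laterality(labels, rng.permutation(cats))[1]
    se = float(null.std(ddof=1) / np.sqrt(n_random)) if n_random > 1 else np.inf
    return LateralityResult(
        per_community=per_comm,
        uncorrected=observed,
        null_expectation=float(null.mean()),
        null_se=se,
        n_randomizations=n_random,
    )


@dataclass(frozen=True)
class RadiusResult:
    """Per-community spatial radii and the normalized size-weighted mean."""

    per_community: np.ndarray   # rho_c, coordinate units
    network_radius: float       # rho of the full node set (normalizer)
    mean_normalized: float      # rho-bar, dimensionless

    def __iter__(self):
        yield from (self.per_community, self.network_radius,
                    self.mean_normalized)


def _cloud_radius(coords: np.ndarray) -> float:
    """Euclidean norm of the per-dimension population standard deviation."""
    return float(np.sqrt(np.sum(coords.var(axis=0, ddof=0))))


def community_radius(partition: Partition,
                     embedding: SpatialEmbedding) -> RadiusResult:
    """Spatial radius of each community and the normalized weighted mean.

    ``rho_c`` is the length of the vector of population standard deviations
    of the community's node coordinates along x, y, z (0 for singletons);
    ``rho_bar = sum_c N_c rho_c / (N rho_net)`` normalizes by the radius of
    the whole node set, so a single all-node community scores exactly 1.
    """
    if embedding.n_nodes != partition.n_nodes:
        raise ValueError("embedding size does not match partition")
    coords = embedding.coordinates
    labels = partition.labels
    k = partition.n_communities
    rho = np.array([_cloud_radius(coords[labels == c]) for c in range(k)])
    rho_net = _cloud_radius(coords)
    if rho_net == 0:
        raise ValueError("degenerate embedding: all nodes coincide")
    sizes = partition.sizes.astype(float)
    mean_norm = float((sizes * rho).sum() / (labels.size * rho_net))
    return RadiusResult(per_community=rho, network_radius=rho_net,
                        mean_normalized=mean_norm)
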