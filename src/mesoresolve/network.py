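"""Core data model for weighted undirected networks and their embeddings.

A network is described by a symmetric, nonnegative, zero-diagonal weight
matrix ``A`` with entries ``w_ij``.  An *edge* is a strictly positive
upper-triangle entry; ``M`` denotes the edge count and ``m`` the total edge
weight (the normalizer of the weighted modularity quality function).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "BinaryGraph",
    "SpatialEmbedding",
    "normalize_weights",
]

#: relative asymmetry tolerated before symmetrization is refused
ASYMMETRY_TOL = 1e-9


def _validate_square(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {matrix.shape}")
    if matrix.shape[0] == 0:
        raise ValueError("empty graph: no nodes")
    return matrix


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric nonnegative weighted graph with zero diagonal.

    Parameters
    ----------
    weights
        ``(n, n)`` array of edge weights ``w_ij >= 0``.  Asymmetry up to a
        relative tolerance of 1e-9 is symmetrized by averaging; larger
        asymmetry raises.  Self-loops are dropped with a warning.
    node_ids
        Ordered node labels; defaults to ``"0" .. "n-1"``.
    """

    weights: np.ndarray
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = _validate_square(self.weights)
        if np.any(w < 0):
            raise ValueError("negative weight in network matrix")
        scale = np.abs(w).max()
        if scale > 0:
            asym = np.abs(w - w.T).max()
            if asym > ASYMMETRY_TOL * scale:
                raise ValueError(
                    f"matrix asymmetry {asym:.3g} exceeds tolerance; "
                    "networks are undirected"
                )
            if asym > 0:
                w = 0.5 * (w + w.T)
        if np.any(np.diag(w) != 0):
            logger.warning("dropping self-loops from input network")
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        if not np.any(w > 0):
            raise ValueError("network has no edges")
        w = np.ascontiguousarray(w)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        ids = self.node_ids
        if ids is None:
            ids = tuple(str(i) for i in range(w.shape[0]))
        else:
            ids = tuple(str(x) for x in ids)
            if len(ids) != w.shape[0]:
                raise ValueError("node_ids length does not match matrix size")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """M: number of strictly positive upper-triangle entries."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu] > 0))

    @property
    def total_weight(self) -> float:
        """m: total edge weight, summed over the upper triangle."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return float(self.weights[iu].sum())

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i (row sums)."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, w) with i < j, in lexicographic pair order."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[i, j] > 0
        return list(zip(i[mask].tolist(), j[mask].tolist(),
                        self.weights[i[mask], j[mask]].tolist()))

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        return WeightedNetwork(weights, node_ids=self.node_ids)


@dataclass(frozen=True)
class BinaryGraph:
    """Symmetric 0/1 graph with zero diagonal (symbol ``B``)."""

    adjacency: np.ndarray
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = _validate_square(self.adjacency)
        if not np.array_equal(b, b.T):
            raise ValueError("binary adjacency must be symmetric")
        if not np.all(np.isin(b, (0.0, 1.0))):
            raise ValueError("binary adjacency entries must be 0 or 1")
        if np.any(np.diag(b) != 0):
            raise ValueError("binary adjacency must have zero diagonal")
        b = np.ascontiguousarray(b)
        b.setflags(write=False)
        object.__setattr__(self, "adjacency", b)
        ids = self.node_ids
        if ids is None:
            ids = tuple(str(i) for i in range(b.shape[0]))
        else:
            ids = tuple(str(x) for x in ids)
            if len(ids) != b.shape[0]:
                raise ValueError("node_ids length does not match matrix size")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass(frozen=True)
class SpatialEmbedding:
    """Per-node 3-D coordinates and optional binary category labels.

    The category typically encodes hemisphere membership (left/right); any
    two-valued label works.  ``categories`` is ``None`` when the metadata
    carried coordinates only, in which case laterality is undefined.
    """

    coordinates: np.ndarray
    categories: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        coords = np.ascontiguousarray(coords)
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)
        if self.categories is not None:
            cats = np.asarray(self.categories)
            if cats.shape != (coords.shape[0],):
                raise ValueError("one category label per node required")
            values = np.unique(cats)
            if len(values) > 2:
                raise ValueError(
                    f"exactly two category values allowed, got {len(values)}"
                )
            # store as 0/1 against the sorted pair of observed values
            binary = np.ascontiguousarray((cats == values[-1]).astype(np.int8))
            binary.setflags(write=False)
            object.__setattr__(self, "categories", binary)

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    @property
    def has_categories(self) -> bool:
        return self.categories is not None


def normalize_weights(net: WeightedNetwork) -> WeightedNetwork:
    """Divide all weights by the maximum weight, mapping them into [0, 1].

    Idempotent and order-preserving; zeros (non-edges) are preserved.  This
    is the normalization applied before soft thresholding so that the power
    map ``w -> w**r`` keeps weights in the unit interval.
    """
    wmax = float(net.weights.max())
    if wmax <= 0:
        raise ValueError("cannot normalize an all-zero network")
    if wmax == 1.0:
        return net
    return net.with_weights(net.weights / wmax)
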