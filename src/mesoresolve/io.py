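"""Readers and writers for networks, node metadata, and diagnostic curves.

Formats are deliberately plain text:

* dense matrix: CSV/TSV square numeric table, optional header row/column of
  node labels;
* edge list: whitespace- or tab-delimited ``node_i node_j weight`` rows,
  ``#`` comments allowed; node order is lexicographic first appearance;
* metadata: TSV with header ``node x y z [category]``;
* curves: TSV with a commented header carrying curve metadata.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BinaryGraph, SpatialEmbedding, WeightedNetwork

__all__ = [
    "read_weighted_matrix",
    "read_node_metadata",
    "write_network",
    "write_edge_list",
    "write_curve",
    "read_curve",
]


def _read_matrix_dialect(path: Path) -> WeightedNetwork:
    text = path.read_text()
    sep = "," if "," in text.splitlines()[0] else None
    df = pd.read_csv(_io.StringIO(text), sep=sep, header=None,
                     engine="python", comment="#")
    node_ids = None
    # header row present when the first cell is not numeric, or when the
    # table has one more row than columns (numeric node labels)
    first = df.iloc[0, 0]
    try:
        float(first)
        if df.shape[0] == df.shape[1] + 1:
            raise ValueError("numeric header row")
    except (TypeError, ValueError):
        header = [str(x) for x in df.iloc[0].tolist()]
        df = df.iloc[1:].reset_index(drop=True)
        node_ids = header
    try:
        values = df.astype(float).to_numpy()
    except ValueError:
        # leading label column (header's corner cell, if any, is discarded)
        node_ids = [str(x) for x in df.iloc[:, 0].tolist()]
        values = df.iloc[:, 1:].astype(float).to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"matrix file is not square: shape {values.shape}"
        )
    return WeightedNetwork(values, node_ids=node_ids)


def _read_edgelist_dialect(path: Path) -> WeightedNetwork:
    rows: list[tuple[str, str, float]] = []
    order: dict[str, int] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"edge list rows need 3 columns, got: {line!r}")
        a, b, w = parts[0], parts[1], float(parts[2])
        for label in (a, b):
            if label not in order:
                order[label] = len(order)
        rows.append((a, b, w))
    if not rows:
        raise ValueError("empty graph: edge list has no edges")
    n = len(order)
    weights = np.zeros((n, n))
    for a, b, w in rows:
        if w < 0:
            raise ValueError(f"negative weight on edge ({a}, {b})")
        i, j = order[a], order[b]
        weights[i, j] = w
        weights[j, i] = w
    return WeightedNetwork(weights, node_ids=list(order))


def read_weighted_matrix(path, dialect: str = "matrix") -> WeightedNetwork:
    """Read a weighted network from a dense matrix or three-column edge list."""
    path = Path(path)
    if dialect == "matrix":
        return _read_matrix_dialect(path)
    if dialect == "edgelist":
        return _read_edgelist_dialect(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'matrix' or 'edgelist'")


def read_node_metadata(path, net: WeightedNetwork | None = None) -> SpatialEmbedding:
    """Read per-node coordinates (and optional binary category) from TSV.

    With ``net`` given, rows are aligned to the network's node order and a
    node-count mismatch is an error.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    for required in ("node", "x", "y", "z"):
        if required not in cols:
            raise ValueError(f"metadata file missing column {required!r}")
    df["node"] = df["node"].astype(str)
    if net is not None:
        if len(df) != net.n_nodes:
            raise ValueError(
                f"metadata has {len(df)} nodes, network has {net.n_nodes}"
            )
        df = df.set_index("node").loc[list(net.node_ids)].reset_index()
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    cats = df["category"].to_numpy() if "category" in cols else None
    return SpatialEmbedding(coords, categories=cats)


def write_network(net: WeightedNetwork, path, labels: bool = True) -> None:
    """Write a network as a dense TSV matrix with a node-label header."""
    path = Path(path)
    with open(path, "w") as fh:
        if labels:
            fh.write("\t".join(net.node_ids) + "\n")
        for row in net.weights:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_edge_list(graph: BinaryGraph | WeightedNetwork, path) -> None:
    """Write a graph as a three-column edge list (weight 1 for binary graphs)."""
    path = Path(path)
    if isinstance(graph, BinaryGraph):
        mat = graph.adjacency
    else:
        mat = graph.weights
    i, j = np.triu_indices(mat.shape[0], k=1)
    mask = mat[i, j] > 0
    with open(path, "w") as fh:
        fh.write("# node_i\tnode_j\tweight\n")
        for a, b in zip(i[mask], j[mask]):
            fh.write(
                f"{graph.node_ids[a]}\t{graph.node_ids[b]}\t{repr(float(mat[a, b]))}\n"
            )


def write_curve(curve, path) -> None:
    """Write an MRF curve as a self-describing TSV table.

    Columns: control-parameter value, mean diagnostic, dispersion (SD),
    number of samples per point.  Round-trips losslessly via
    :func:`read_curve` (floats written with ``repr``).
    """
    if len(curve.grid) == 0:
        raise ValueError("cannot write a curve with an empty grid")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# control={curve.control_name}\tdiagnostic={curve.diagnostic_name}\n")
        fh.write(f"{curve.control_name}\tvalue\tdispersion\tn_samples\n")
        for g, v, d, n in zip(curve.grid, curve.values, curve.dispersion,
                              curve.n_samples):
            fh.write(f"{repr(float(g))}\t{repr(float(v))}\t{repr(float(d))}\t{int(n)}\n")


def read_curve(path):
    """Read a curve written by :func:`write_curve`."""
    from .mrf import MRFCurve

    path = Path(path)
    lines = path.read_text().splitlines()
    meta = {}
    if lines and lines[0].startswith("#"):
        for item in lines[0][1:].strip().split("\t"):
            key, _, val = item.partition("=")
            meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#")
    return MRFCurve(
        control_name=meta.get("control", df.columns[0]),
        grid=df.iloc[:, 0].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        dispersion=df["dispersion"].to_numpy(dtype=float),
        n_samples=df["n_samples"].to_numpy(dtype=int),
        diagnostic_name=meta.get("diagnostic", "diagnostic"),
    )
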