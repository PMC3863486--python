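"""Build the analyzed unweighted graph from a fiber-count connectivity matrix.

A structural connectome arrives as a symmetric non-negative integer matrix
of streamline counts between ROI pairs.  A single global threshold T
(shared across subjects) binarizes it: ROI pair (i, j) becomes an edge of
the simple graph when its count exceeds T.  Self-loops are ignored and
isolated ROIs stay in the node set, so the graph always has as many nodes
as the matrix has rows.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

__all__ = [
    "InvalidMatrixError",
    "GraphParseError",
    "validate_simple_graph",
    "threshold_connectivity",
    "read_graph",
    "write_graph",
]


class InvalidMatrixError(ValueError):
    """Connectivity matrix violates symmetry/non-negativity requirements."""


class GraphParseError(ValueError):
    """A graph file violates the simple-graph contract."""


def validate_simple_graph(G: nx.Graph) -> nx.Graph:
    """Check the simple-graph contract: nodes 0..N-1, no self-loops."""
    n = G.number_of_nodes()
    if set(G.nodes()) != set(range(n)):
        raise GraphParseError(f"node ids must be 0..{n - 1}")
    if any(u == v for u, v in nx.selfloop_edges(G)):
        raise GraphParseError("self-loops are not allowed")
    return G


def _as_counts(C) -> np.ndarray:
    counts = getattr(C, "counts", C)
    return np.asarray(counts)


def threshold_connectivity(C, T: float, strict: bool = True) -> nx.Graph:
    """Binarize a connectivity matrix at global threshold ``T``.

    Edge {i, j} is created when counts[i, j] > T (or >= T with
    ``strict=False``).  The diagonal is ignored; isolated nodes are kept.

    Raises
    ------
    InvalidMatrixError
        If the matrix is not square, symmetric, and non-negative, or T < 0.
    """
    counts = _as_counts(C)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise InvalidMatrixError(f"matrix must be square, got {counts.shape}")
    if not np.array_equal(counts, counts.T):
        raise InvalidMatrixError("connectivity matrix must be symmetric")
    if np.any(counts < 0):
        raise InvalidMatrixError("connectivity matrix must be non-negative")
    if T < 0:
        raise InvalidMatrixError(f"threshold must be >= 0, got {T}")
    n = counts.shape[0]
    mask = counts > T if strict else counts >= T
    np.fill_diagonal(mask, False)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(np.triu(mask, k=1))
    G.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return G


def write_graph(G: nx.Graph, path, format: str = "edgelist") -> None:
    """Write a simple graph as an edge list ("i j" per line, pairs listed
    once, 0-based) or as an N x N 0/1 adjacency matrix.

    Isolated trailing nodes are preserved in the edge-list format through a
    "# nodes N" header line.
    """
    validate_simple_graph(G)
    n = G.number_of_nodes()
    with open(path, "w") as fh:
        if format == "edgelist":
            fh.write(f"# nodes {n}\n")
            for u, v in sorted((min(e), max(e)) for e in G.edges()):
                fh.write(f"{u} {v}\n")
        elif format == "adjacency":
            A = nx.to_numpy_array(G, nodelist=range(n), dtype=int)
            for row in A:
                fh.write(" ".join(str(int(x)) for x in row) + "\n")
        else:
            raise ValueError(f"unknown format: {format!r}")


def read_graph(path, format: str = "edgelist") -> nx.Graph:
    """Read a graph written by :func:`write_graph`; inverse round-trip.

    Rejects self-loops, duplicate edges, and asymmetric adjacency, naming
    the offending line.
    """
    if format == "edgelist":
        G = nx.Graph()
        n_declared = None
        seen = set()
        max_node = -1
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if len(parts) == 2 and parts[0] == "nodes":
                        n_declared = int(parts[1])
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise GraphParseError(f"{path}:{lineno}: expected 'i j'")
                u, v = int(parts[0]), int(parts[1])
                if u == v:
                    raise GraphParseError(f"{path}:{lineno}: self-loop {u}")
                key = (min(u, v), max(u, v))
                if key in seen:
                    raise GraphParseError(
                        f"{path}:{lineno}: duplicate edge {u} {v}")
                seen.add(key)
                max_node = max(max_node, u, v)
                G.add_edge(u, v)
        n = n_declared if n_declared is not None else max_node + 1
        if max_node >= n:
            raise GraphParseError(
                f"{path}: node id {max_node} exceeds declared count {n}")
        G.add_nodes_from(range(max(n, 0)))
        return validate_simple_graph(G)
    if format == "adjacency":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([int(x) for x in line.split()])
        A = np.array(rows)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise GraphParseError(f"{path}: adjacency matrix must be square")
        bad = np.argwhere(A != A.T)
        if bad.size:
            i, j = bad[0]
            raise GraphParseError(
                f"{path}: asymmetric adjacency at ({i}, {j})")
        if np.any(np.diag(A) != 0):
            raise GraphParseError(f"{path}: nonzero diagonal (self-loop)")
        G = nx.Graph()
        G.add_nodes_from(range(A.shape[0]))
        rs, cs = np.nonzero(np.triu(A, k=1))
        G.add_edges_from(zip(rs.tolist(), cs.tolist()))
        return validate_simple_graph(G)
    raise ValueError(f"unknown format: {format!r}")
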