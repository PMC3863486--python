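"""Global graph properties and model-vs-real difference ratios.

Covers the degree distribution P(k) and its Pearson correlation between
two graphs, characteristic path length, average clustering coefficient
C_i = 2 E_neighbor,i / (k_i (k_i - 1)), global efficiency, the percentage
difference ratios

    PathDiff  = |Path_model - Path_real| / Path_real * 100%
    ClustDiff = |C_model   - C_real|    / C_real    * 100%

and the small-world coefficient sigma = (C/C_rand) / (L/L_rand) against an
Erdos-Renyi G(N, m) reference ensemble.

Path-length conventions on disconnected graphs: the characteristic path
length averages over connected node pairs only, while global efficiency
counts disconnected pairs as zero contribution (so it remains meaningful
on fragmented networks).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .construction import validate_simple_graph
from .models import CalibrationTarget, generate_er

__all__ = [
    "MetricUndefinedError",
    "degree_distribution",
    "pearson_degree_correlation",
    "characteristic_path_length",
    "average_clustering",
    "global_efficiency",
    "path_diff",
    "clust_diff",
    "small_worldness",
    "global_summary",
]


class MetricUndefinedError(ValueError):
    """A metric is undefined for the given input (e.g. zero variance)."""


def degree_distribution(G: nx.Graph) -> np.ndarray:
    """Empirical degree distribution P(k), k = 0..k_max; sums to 1."""
    validate_simple_graph(G)
    degs = [d for _, d in G.degree()]
    return np.bincount(degs) / G.number_of_nodes()


def pearson_degree_correlation(G: nx.Graph, H: nx.Graph) -> float:
    """Pearson correlation between two degree distributions.

    The P(k) vectors are aligned on k = 0..max(k_max) with zero padding.
    Raises :exc:`MetricUndefinedError` when either padded vector has zero
    variance (the correlation is then undefined).
    """
    pg, ph = degree_distribution(G), degree_distribution(H)
    m = max(pg.size, ph.size)
    pg = np.pad(pg, (0, m - pg.size))
    ph = np.pad(ph, (0, m - ph.size))
    if np.ptp(pg) == 0 or np.ptp(ph) == 0:
        raise MetricUndefinedError(
            "degree-distribution correlation undefined: constant P(k) vector")
    return float(np.corrcoef(pg, ph)[0, 1])


def _distance_matrix(G: nx.Graph) -> np.ndarray:
    n = G.number_of_nodes()
    if G.number_of_edges() == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    rows, cols = zip(*G.edges())
    data = np.ones(len(rows))
    A = csr_array((np.concatenate([data, data]),
                   (np.array(rows + cols), np.array(cols + rows))),
                  shape=(n, n))
    return shortest_path(A, method="D", unweighted=True, directed=False)


def characteristic_path_length(G: nx.Graph,
                               disconnected: str = "connected-pairs") -> float:
    """Mean shortest-path length.

    ``disconnected`` selects the convention on fragmented graphs:
    "connected-pairs" (default) averages over reachable pairs only;
    "largest-component" restricts to the largest connected component.
    Returns NaN when no pair is connected.
    """
    validate_simple_graph(G)
    if G.number_of_nodes() < 2:
        return float("nan")
    if disconnected == "largest-component":
        comp = max(nx.connected_components(G), key=len)
        G = nx.convert_node_labels_to_integers(G.subgraph(comp))
        if G.number_of_nodes() < 2:
            return float("nan")
    elif disconnected != "connected-pairs":
        raise ValueError(f"unknown convention: {disconnected!r}")
    d = _distance_matrix(G)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def average_clustering(G: nx.Graph) -> float:
    """Mean clustering coefficient over all nodes; C_i = 0 for degree < 2."""
    validate_simple_graph(G)
    if G.number_of_nodes() == 0:
        return float("nan")
    return nx.average_clustering(G, count_zeros=True)


def global_efficiency(G: nx.Graph) -> float:
    """Mean inverse shortest-path length over all ordered node pairs;
    disconnected pairs contribute zero."""
    validate_simple_graph(G)
    n = G.number_of_nodes()
    if n < 2:
        raise MetricUndefinedError("global efficiency needs >= 2 nodes")
    d = _distance_matrix(G)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1) / 2))


def path_diff(path_model: float, path_real: float) -> float:
    """|Path_model - Path_real| / Path_real, as a percentage."""
    if not path_real > 0:
        raise MetricUndefinedError("path_real must be positive")
    return abs(path_model - path_real) / path_real * 100.0


def clust_diff(c_model: float, c_real: float) -> float:
    """|C_model - C_real| / C_real, as a percentage."""
    if not c_real > 0:
        raise MetricUndefinedError("c_real must be positive")
    return abs(c_model - c_real) / c_real * 100.0


def small_worldness(G: nx.Graph, n_random: int = 20, seed=0) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C_rand and L_rand are means over ``n_random`` Erdos-Renyi G(N, m)
    graphs with the input's node and edge counts.  sigma > 1 indicates a
    network more clustered than random at comparable path length.
    """
    validate_simple_graph(G)
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    target = CalibrationTarget.from_graph(G)
    rng = np.random.default_rng(seed)
    c = average_clustering(G)
    l = characteristic_path_length(G)
    cr, lr = [], []
    for _ in range(n_random):
        R = generate_er(target, seed=rng)
        cr.append(average_clustering(R))
        lr.append(characteristic_path_length(R))
    c_rand, l_rand = float(np.mean(cr)), float(np.mean(lr))
    if not (c_rand > 0) or not (l_rand > 0) or np.isnan(l):
        raise MetricUndefinedError(
            "small-worldness undefined: degenerate random reference")
    return (c / c_rand) / (l / l_rand)


def global_summary(G: nx.Graph, n_random: int = 20, seed=0) -> dict:
    """All global properties of one graph as a plain dict."""
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "char_path_length": characteristic_path_length(G),
        "avg_clustering": average_clustering(G),
        "global_efficiency": global_efficiency(G),
        "small_worldness": small_worldness(G, n_random=n_random, seed=seed),
        "degree_distribution": degree_distribution(G).tolist(),
    }
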