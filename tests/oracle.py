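"""Independent brute-force oracles for graphlet statistics.

Everything here deliberately avoids the package's counting path: subsets
are enumerated with itertools, connectivity and isomorphism are delegated
to networkx, and the similarity formulas are re-implemented step by step.
Only usable for small graphs (N <= ~12).
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher


def brute_counts_and_orbits(G, catalog):
    """Exact graphlet counts and per-node orbit touches by enumerating all
    node subsets of size 2..5 and classifying each induced subgraph with
    networkx isomorphism tests."""
    counts = np.zeros(catalog.n_graphlets, dtype=np.int64)
    touch = np.zeros((G.number_of_nodes(), catalog.n_orbits), dtype=np.int64)
    nodes = sorted(G.nodes())
    by_size = {}
    for gid, glet in enumerate(catalog.graphlets):
        by_size.setdefault(glet.number_of_nodes(), []).append(gid)
    for k in range(2, 6):
        for subset in itertools.combinations(nodes, k):
            sg = G.subgraph(subset)
            if not nx.is_connected(sg):
                continue
            for gid in by_size[k]:
                glet = catalog.graphlets[gid]
                if glet.number_of_edges() != sg.number_of_edges():
                    continue
                gm = GraphMatcher(sg, glet)
                if gm.is_isomorphic():
                    counts[gid] += 1
                    for v, pos in gm.mapping.items():
                        touch[v, catalog.node_orbit[gid][pos]] += 1
                    break
    return counts, touch


def brute_rgf_distance(G, H, catalog, include_edge=True):
    """RGF distance evaluated directly from brute-force counts."""
    cg, _ = brute_counts_and_orbits(G, catalog)
    ch, _ = brute_counts_and_orbits(H, catalog)
    sizes = [g.number_of_nodes() for g in catalog.graphlets]
    total = 0.0
    idx = [i for i in range(catalog.n_graphlets)
           if include_edge or sizes[i] > 2]
    ag = [max(cg[i], 1) for i in idx]
    ah = [max(ch[i], 1) for i in idx]
    tg, th = sum(ag), sum(ah)
    for a, b in zip(ag, ah):
        total += abs(-math.log(a / tg) - (-math.log(b / th)))
    return total


def brute_gdd_agreement(G, H, catalog, mean_type="arithmetic"):
    """GDD agreement evaluated step by step from brute-force orbit touches."""
    _, tg = brute_counts_and_orbits(G, catalog)
    _, th = brute_counts_and_orbits(H, catalog)
    ags = []
    for j in range(catalog.n_orbits):
        dists = []
        for touch in (tg, th):
            col = touch[:, j]
            ks = sorted(set(int(x) for x in col if x > 0))
            if not ks:
                dists.append(None)
                continue
            scaled = {k: sum(1 for x in col if x == k) / k for k in ks}
            tot = sum(scaled.values())
            dists.append({k: v / tot for k, v in scaled.items()})
        a, b = dists
        if a is None and b is None:
            ags.append(1.0)
            continue
        a = a or {}
        b = b or {}
        sq = sum((a.get(k, 0.0) - b.get(k, 0.0)) ** 2
                 for k in set(a) | set(b))
        ags.append(1.0 - math.sqrt(sq) / math.sqrt(2.0))
    if mean_type == "arithmetic":
        return sum(ags) / len(ags)
    if any(a <= 0 for a in ags):
        return 0.0
    return math.exp(sum(math.log(a) for a in ags) / len(ags))
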