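"""Graphlet catalog, exact graphlet counting, and graphlet-based similarity.

A *graphlet* is a small connected non-isomorphic graph; on 2-5 nodes there
are exactly 30 of them.  Each graphlet's nodes fall into *automorphism
orbits* (topologically equivalent positions); across the whole catalog
there are 73 orbits.  Two networks are compared either by the relative
frequencies of the 30 graphlets (RGF distance) or by the per-orbit
distributions of node touch counts (GDD agreement).

Counting is exact: every connected induced subgraph on 2-5 nodes is
enumerated once via the ESU tree (grow a subset from each root using only
higher-numbered exclusive neighbours) and classified through a precomputed
lookup table over all labeled graphs on <=5 nodes.  The enumeration kernel
is compiled with numba; the table build is pure Python and cached.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from numba import njit

from .construction import validate_simple_graph

__all__ = [
    "GraphletCatalog",
    "build_catalog",
    "count_graphlets",
    "orbit_degree_vectors",
    "rgf_distance",
    "gdd_agreement",
    "GraphletUndefinedError",
]

MAX_GRAPHLET_NODES = 5


class GraphletUndefinedError(ValueError):
    """Raised when a graphlet-based metric is undefined for the input."""


def _pair_bits(k: int) -> dict[tuple[int, int], int]:
    """Map unordered node-pair (i<j) on k nodes to a bit position."""
    bits = {}
    b = 0
    for i in range(k):
        for j in range(i + 1, k):
            bits[(i, j)] = b
            b += 1
    return bits


def _relabel_mask(mask: int, perm: tuple[int, ...], bits: dict) -> int:
    out = 0
    for (i, j), b in bits.items():
        if mask >> b & 1:
            pi, pj = perm[i], perm[j]
            if pi > pj:
                pi, pj = pj, pi
            out |= 1 << bits[(pi, pj)]
    return out


def _is_connected_mask(mask: int, k: int, bits: dict) -> bool:
    reach = 1  # bitset of reached nodes, start at node 0
    frontier = [0]
    adj = [[] for _ in range(k)]
    for (i, j), b in bits.items():
        if mask >> b & 1:
            adj[i].append(j)
            adj[j].append(i)
    while frontier:
        v = frontier.pop()
        for u in adj[v]:
            if not reach >> u & 1:
                reach |= 1 << u
                frontier.append(u)
    return reach == (1 << k) - 1


@dataclass(frozen=True)
class GraphletCatalog:
    """The canonical 2-5-node graphlet catalog with automorphism orbits.

    Ordering is deterministic and documented: graphlets sorted by
    (node count, edge count, canonical edge-bitmask); within a graphlet,
    orbits sorted by their smallest canonical node label.  This places the
    single edge first, so global orbit 0 is the edge endpoint and a node's
    orbit-0 touch count equals its degree.
    """

    graphlets: tuple  # tuple of nx.Graph, canonical node labels 0..k-1
    orbits: tuple  # per graphlet, tuple of orbits (each a tuple of nodes)
    node_orbit: tuple  # per graphlet, tuple mapping node -> global orbit id
    n_orbits: int
    # counting lookup tables (labeled-graph mask -> graphlet id / orbit ids)
    _type_tables: dict = field(repr=False, default_factory=dict)
    _orbit_tables: dict = field(repr=False, default_factory=dict)

    @property
    def n_graphlets(self) -> int:
        return len(self.graphlets)

    def sizes(self) -> np.ndarray:
        return np.array([g.number_of_nodes() for g in self.graphlets])

    def orbit_sizes(self) -> np.ndarray:
        """Size of each global orbit (number of equivalent graphlet nodes)."""
        out = np.zeros(self.n_orbits, dtype=int)
        for gi, orbs in enumerate(self.orbits):
            for orb in orbs:
                out[self.node_orbit[gi][orb[0]]] = len(orb)
        return out

    def orbit_graphlet(self) -> np.ndarray:
        """Graphlet id owning each global orbit."""
        out = np.zeros(self.n_orbits, dtype=int)
        for gi, nmap in enumerate(self.node_orbit):
            for oid in nmap:
                out[oid] = gi
        return out


@lru_cache(maxsize=1)
def build_catalog() -> GraphletCatalog:
    """Enumerate all connected simple graphs on 2-5 nodes and their orbits.

    All labeled graphs on k=2..5 nodes are generated as edge bitmasks,
    filtered to connected, and deduplicated by the minimum bitmask over all
    node permutations (a canonical form).  Orbits come from the brute-force
    automorphism group of each canonical graph.
    """
    graphlets: list[nx.Graph] = []
    orbits: list[tuple] = []
    node_orbit: list[tuple] = []
    type_tables: dict[int, np.ndarray] = {}
    orbit_tables: dict[int, np.ndarray] = {}
    canon_index: dict[tuple[int, int], int] = {}  # (k, canonical mask) -> id
    next_orbit = 0

    for k in range(2, MAX_GRAPHLET_NODES + 1):
        bits = _pair_bits(k)
        n_bits = k * (k - 1) // 2
        perms = list(itertools.permutations(range(k)))
        # canonicalize every connected labeled graph on k nodes
        canon: dict[int, tuple[int, tuple]] = {}  # mask -> (cmask, witness perm)
        for mask in range(1, 1 << n_bits):
            if not _is_connected_mask(mask, k, bits):
                continue
            best, wit = None, None
            for p in perms:
                m = _relabel_mask(mask, p, bits)
                if best is None or m < best:
                    best, wit = m, p
            canon[mask] = (best, wit)

        cmasks = sorted({c for c, _ in canon.values()},
                        key=lambda m: (bin(m).count("1"), m))
        for cm in cmasks:
            g = nx.Graph()
            g.add_nodes_from(range(k))
            g.add_edges_from(e for e, b in bits.items() if cm >> b & 1)
            gid = len(graphlets)
            canon_index[(k, cm)] = gid
            graphlets.append(g)
            # automorphism orbits: i ~ p(i) for every automorphism p
            parent = list(range(k))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for p in perms:
                if _relabel_mask(cm, p, bits) == cm:
                    for i in range(k):
                        ri, rj = find(i), find(p[i])
                        if ri != rj:
                            parent[max(ri, rj)] = min(ri, rj)
            groups: dict[int, list[int]] = {}
            for i in range(k):
                groups.setdefault(find(i), []).append(i)
            orbs = tuple(tuple(groups[r]) for r in sorted(groups))
            orbits.append(orbs)
            nmap = [0] * k
            for orb in orbs:
                for v in orb:
                    nmap[v] = next_orbit
                next_orbit += 1
            node_orbit.append(tuple(nmap))

        # lookup tables over all labeled masks for the counting kernel
        ttab = np.full(1 << n_bits, -1, dtype=np.int64)
        otab = np.full((1 << n_bits, k), -1, dtype=np.int64)
        for mask, (cm, p) in canon.items():
            gid = canon_index[(k, cm)]
            ttab[mask] = gid
            nmap = node_orbit[gid]
            for i in range(k):
                otab[mask, i] = nmap[p[i]]
        type_tables[k] = ttab
        orbit_tables[k] = otab

    return GraphletCatalog(
        graphlets=tuple(graphlets),
        orbits=tuple(orbits),
        node_orbit=tuple(node_orbit),
        n_orbits=next_orbit,
        _type_tables=type_tables,
        _orbit_tables=orbit_tables,
    )


@njit(cache=True)
def _esu_kernel(n, indptr, indices, adj, t3, o3, t4, o4, t5, o5,
                counts, orbit_touch):  # pragma: no cover - compiled
    """Enumerate every connected induced subgraph on 2-5 nodes exactly once.

    ESU tree: from each root, extend with exclusive neighbours carrying a
    label greater than the root.  Each tree node of size s>=2 is one induced
    connected subset; it is classified by its edge bitmask via the lookup
    tables and accumulated into graphlet counts and per-node orbit touches.
    """
    sub = np.empty(5, np.int64)
    ext = np.empty((6, n), np.int64)
    ext_len = np.zeros(6, np.int64)
    for root in range(n):
        sub[0] = root
        l = 0
        for ii in range(indptr[root], indptr[root + 1]):
            u = indices[ii]
            if u > root:
                ext[1, l] = u
                l += 1
        ext_len[1] = l
        depth = 1
        while depth >= 1:
            if ext_len[depth] == 0:
                depth -= 1
                continue
            ext_len[depth] -= 1
            w = ext[depth, ext_len[depth]]
            sub[depth] = w
            size = depth + 1
            if size == 2:
                counts[0] += 1
                orbit_touch[root, 0] += 1
                orbit_touch[w, 0] += 1
            else:
                mask = 0
                b = 0
                for i in range(size):
                    for j in range(i + 1, size):
                        if adj[sub[i], sub[j]]:
                            mask |= 1 << b
                        b += 1
                if size == 3:
                    counts[t3[mask]] += 1
                    for i in range(3):
                        orbit_touch[sub[i], o3[mask, i]] += 1
                elif size == 4:
                    counts[t4[mask]] += 1
                    for i in range(4):
                        orbit_touch[sub[i], o4[mask, i]] += 1
                else:
                    counts[t5[mask]] += 1
                    for i in range(5):
                        orbit_touch[sub[i], o5[mask, i]] += 1
            if size < 5:
                nl = ext_len[depth]
                for j in range(nl):
                    ext[depth + 1, j] = ext[depth, j]
                l2 = nl
                for ii in range(indptr[w], indptr[w + 1]):
                    u = indices[ii]
                    if u <= root:
                        continue
                    ok = True
                    for s2 in range(size - 1):  # sub before w was added
                        if u == sub[s2] or adj[u, sub[s2]]:
                            ok = False
                            break
                    if ok:
                        ext[depth + 1, l2] = u
                        l2 += 1
                ext_len[depth + 1] = l2
                depth += 1


def _graph_arrays(G: nx.Graph):
    n = G.number_of_nodes()
    adj = np.zeros((n, n), dtype=np.bool_)
    for u, v in G.edges():
        adj[u, v] = True
        adj[v, u] = True
    degs = adj.sum(axis=1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(degs, out=indptr[1:])
    indices = np.nonzero(adj)[1].astype(np.int64)
    return n, indptr, indices, adj


def _count_both(G: nx.Graph, catalog: GraphletCatalog):
    validate_simple_graph(G)
    n, indptr, indices, adj = _graph_arrays(G)
    counts = np.zeros(catalog.n_graphlets, dtype=np.int64)
    touch = np.zeros((n, catalog.n_orbits), dtype=np.int64)
    if n >= 2:
        _esu_kernel(n, indptr, indices, adj,
                    catalog._type_tables[3], catalog._orbit_tables[3],
                    catalog._type_tables[4], catalog._orbit_tables[4],
                    catalog._type_tables[5], catalog._orbit_tables[5],
                    counts, touch)
    return counts, touch


def count_graphlets(G: nx.Graph, catalog: GraphletCatalog | None = None) -> np.ndarray:
    """Exact induced-subgraph counts of each catalog graphlet in ``G``.

    Returns an integer vector indexed by graphlet id; entry 0 (the edge
    graphlet) equals the number of edges of ``G``.
    """
    catalog = catalog or build_catalog()
    counts, _ = _count_both(G, catalog)
    return counts


def orbit_degree_vectors(G: nx.Graph, catalog: GraphletCatalog | None = None) -> np.ndarray:
    """Per-node orbit touch counts: out[v, o] is the number of induced
    graphlet occurrences in which node ``v`` sits at orbit ``o``.

    Column 0 equals the degree sequence.
    """
    catalog = catalog or build_catalog()
    _, touch = _count_both(G, catalog)
    return touch


def rgf_distance(G: nx.Graph, H: nx.Graph,
                 catalog: GraphletCatalog | None = None,
                 include_edge: bool = True) -> float:
    """Relative graphlet frequency distance between two graphs.

    D(G,H) = sum_i |F_i(G) - F_i(H)| with F_i(X) = -log(N_i(X)/T(X)),
    where N_i are graphlet counts and T the total.  All 30 graphlets enter
    the sum by default; ``include_edge=False`` drops the 2-node edge
    graphlet, restoring the 29-constraint variant.  Zero counts are
    replaced by 1 before normalization so every F_i is finite.
    """
    catalog = catalog or build_catalog()
    cg = count_graphlets(G, catalog).astype(float)
    ch = count_graphlets(H, catalog).astype(float)
    if not include_edge:
        keep = catalog.sizes() > 2
        cg, ch = cg[keep], ch[keep]
    if cg.sum() == 0 or ch.sum() == 0:
        raise GraphletUndefinedError(
            "RGF distance undefined: a graph contains no graphlets")
    cg[cg == 0] = 1.0
    ch[ch == 0] = 1.0
    fg = -np.log(cg / cg.sum())
    fh = -np.log(ch / ch.sum())
    return float(np.abs(fg - fh).sum())


def _orbit_distribution(touch_col: np.ndarray) -> np.ndarray | None:
    """Scaled, normalized distribution N^j(k) of touch counts k>=1.

    Returns None when no node touches the orbit (empty distribution).
    """
    pos = touch_col[touch_col > 0]
    if pos.size == 0:
        return None
    kmax = int(pos.max())
    d = np.bincount(pos, minlength=kmax + 1)[1:].astype(float)
    s = d / np.arange(1, kmax + 1)
    return s / s.sum()


def gdd_agreement(G: nx.Graph, H: nx.Graph,
                  catalog: GraphletCatalog | None = None,
                  mean_type: str = "arithmetic") -> float:
    """Graphlet degree distribution agreement in [0, 1].

    For each of the 73 orbits, the distribution of per-node touch counts is
    scaled by 1/k, normalized, and compared via Euclidean distance
    D^j = (1/sqrt(2))*||N_G^j - N_H^j||_2; orbit agreement is 1 - D^j, and
    the total is the arithmetic (default) or geometric mean over orbits.
    Orbits untouched in both graphs agree perfectly (identical empty
    distributions); an orbit touched in only one graph is compared against
    the zero vector.
    """
    if mean_type not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean_type: {mean_type!r}")
    catalog = catalog or build_catalog()
    tg = orbit_degree_vectors(G, catalog)
    th = orbit_degree_vectors(H, catalog)
    agreements = np.empty(catalog.n_orbits)
    for j in range(catalog.n_orbits):
        ng = _orbit_distribution(tg[:, j])
        nh = _orbit_distribution(th[:, j])
        if ng is None and nh is None:
            agreements[j] = 1.0
            continue
        if ng is None:
            ng = np.zeros(1)
        if nh is None:
            nh = np.zeros(1)
        m = max(ng.size, nh.size)
        ng = np.pad(ng, (0, m - ng.size))
        nh = np.pad(nh, (0, m - nh.size))
        d = np.sqrt(((ng - nh) ** 2).sum()) / np.sqrt(2.0)
        agreements[j] = 1.0 - d
    if mean_type == "arithmetic":
        return float(agreements.mean())
    if np.any(agreements <= 0):
        return 0.0
    return float(np.exp(np.log(agreements).mean()))
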