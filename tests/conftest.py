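import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from connectofit import build_catalog, count_graphlets


@pytest.fixture(scope="session")
def catalog():
    """Session-wide graphlet catalog; the first count also warms up the
    compiled enumeration kernel."""
    cat = build_catalog()
    count_graphlets(nx.path_graph(3), cat)
    return cat


@pytest.fixture(scope="session")
def random_graphs():
    """A reproducible batch of small random graphs (N <= 12) spanning
    sparse to dense densities, for oracle-equivalence checks."""
    rng = np.random.default_rng(20240917)
    graphs = []
    while len(graphs) < 220:
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.1, 0.8))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        graphs.append(nx.convert_node_labels_to_integers(G))
    return graphs
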