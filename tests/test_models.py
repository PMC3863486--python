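import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from connectofit import (
    CalibrationTarget,
    ModelSpec,
    generate_er,
    generate_erdd,
    generate_geo,
    generate_geo_gd,
    generate_instances,
    generate_sf,
    generate_sf_gd,
    generate_sticky,
)
from connectofit.models import _any_degree_sequence


def target(n, m):
    return CalibrationTarget(n, m, _any_degree_sequence(n, m))


def degree_target(degs):
    return CalibrationTarget(len(degs), sum(degs) // 2, tuple(degs))


def assert_simple(G, n):
    assert G.number_of_nodes() == n
    assert set(G.nodes()) == set(range(n))
    assert not any(u == v for u, v in G.edges())


class TestER:
    def test_complete_graph_is_only_possibility(self):
        G = generate_er(target(5, 10), seed=0)
        assert nx.is_isomorphic(G, nx.complete_graph(5))

    def test_empty_graph(self):
        assert generate_er(target(10, 0), seed=1).number_of_edges() == 0

    def test_exact_edge_count_over_many_seeds(self):
        for seed in range(100):
            G = generate_er(target(50, 100), seed=seed)
            assert_simple(G, 50)
            assert G.number_of_edges() == 100

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            generate_er(CalibrationTarget(3, 4, (3, 3, 2)), seed=0)

    def test_uniformity_over_labeled_two_edge_graphs(self):
        """G(3 nodes, 2 edges) has three labeled outcomes, each with
        probability 1/3; a chi-square over 30,000 draws must not reject."""
        counts = {}
        for seed in range(30000):
            G = generate_er(target(3, 2), seed=seed)
            key = tuple(sorted(map(tuple, map(sorted, G.edges()))))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        _, p = chisquare(list(counts.values()))
        assert p > 0.001


class TestERDD:
    @pytest.mark.parametrize("degs,expected", [
        ([2, 2, 2], nx.cycle_graph(3)),
        ([1, 1], nx.path_graph(2)),
        ([3, 1, 1, 1], nx.star_graph(3)),
    ])
    def test_unique_realizations(self, degs, expected):
        G = generate_erdd(degree_target(degs), seed=0)
        assert nx.is_isomorphic(G, expected)

    def test_exact_degree_sequence_on_random_inputs(self):
        for seed in range(30):
            real = nx.gnm_random_graph(60, 150, seed=seed)
            tgt = CalibrationTarget.from_graph(real)
            G = generate_erdd(tgt, seed=seed)
            assert_simple(G, 60)
            assert tuple(G.degree(v) for v in range(60)) == tgt.degree_sequence

    def test_non_graphical_sequence_rejected(self):
        with pytest.raises(ValueError, match="graphical"):
            generate_erdd(CalibrationTarget(2, 2, (3, 1)), seed=0)


class TestGEO:
    def test_two_nodes_one_edge(self):
        G = generate_geo(target(2, 1), seed=0)
        assert G.number_of_edges() == 1

    def test_complete_when_all_pairs_requested(self):
        G = generate_geo(target(6, 15), seed=0)
        assert nx.is_isomorphic(G, nx.complete_graph(6))

    def test_exact_edge_count_over_many_seeds(self):
        for seed in range(50):
            G = generate_geo(target(100, 300), seed=seed)
            assert_simple(G, 100)
            assert G.number_of_edges() == 300

    def test_edges_are_the_closest_pairs(self):
        """Edges correspond to thresholding Euclidean distance: every edge
        is no longer than every non-edge."""
        from scipy.spatial.distance import squareform, pdist
        G = generate_geo(target(30, 60), seed=7)
        # the generator draws its points as the first rng output, so the
        # same seed recovers the exact point set
        pts = np.random.default_rng(7).random((30, 3))
        D = squareform(pdist(pts))
        edge_d = [D[u, v] for u, v in G.edges()]
        non_edge_d = [D[u, v] for u in range(30) for v in range(u + 1, 30)
                      if not G.has_edge(u, v)]
        assert max(edge_d) <= min(non_edge_d) + 1e-12


class TestGEOGD:
    def test_seed_sized_graph_is_pure_geometric(self):
        G = generate_geo_gd(target(5, 6), seed=1, seed_size=5)
        H = generate_geo(target(5, 6), seed=1)
        # same uniform points, same cutoff rule
        assert set(G.edges()) == set(H.edges())

    def test_child_with_tiny_epsilon_sits_next_to_parent(self):
        """With a negligible mutation radius each duplicated point is
        coincident with its parent, so it picks up its parent's
        within-cutoff neighbourhood; the realized edges are the requested
        number of closest pairs of the duplication point process."""
        eps = 1e-9
        G = generate_geo_gd(target(40, 100), seed=2, epsilon=eps,
                            seed_size=5)
        # replay the documented placement process to recover the points
        rng = np.random.default_rng(2)
        pts = np.empty((40, 3))
        pts[:5] = rng.random((5, 3))
        parents = {}
        for i in range(5, 40):
            parents[i] = int(rng.integers(i))
            pts[i] = np.mod(pts[parents[i]] + rng.uniform(-eps, eps, 3), 1.0)
        for child, parent in parents.items():
            assert np.linalg.norm(pts[child] - pts[parent]) < 2e-9
        assert G.number_of_edges() == 100
        # the 100 closest pairs are all intra-cluster: every edge joins two
        # near-coincident duplicates, never two different seed clusters
        from scipy.spatial.distance import squareform, pdist
        D = squareform(pdist(pts))
        assert all(D[u, v] < 1e-6 for u, v in G.edges())

    def test_large_epsilon_limit_matches_geo_degrees(self):
        """epsilon >> 1 scatters children uniformly-ish; the degree
        distribution must be statistically indistinguishable from GEO."""
        deg_gd, deg_geo = [], []
        for seed in range(50):
            gd = generate_geo_gd(target(60, 150), seed=seed, epsilon=50.0)
            geo = generate_geo(target(60, 150), seed=1000 + seed)
            deg_gd.extend(d for _, d in gd.degree())
            deg_geo.extend(d for _, d in geo.degree())
        _, p = ks_2samp(deg_gd, deg_geo)
        assert p > 0.01

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            generate_geo_gd(target(10, 20), seed=0, epsilon=0.0)


class TestSF:
    def test_seed_clique_returned_at_minimal_size(self):
        G = generate_sf(target(3, 6), seed=0, m=2)
        assert nx.is_isomorphic(G, nx.complete_graph(3))

    def test_edge_count_formula(self):
        for n, m in [(50, 2), (100, 3), (40, 1)]:
            G = generate_sf(target(n, m * n), seed=n, m=m)
            m0 = m + 1
            assert G.number_of_edges() == m0 * (m0 - 1) // 2 + m * (n - m0)
            assert_simple(G, n)

    def test_too_sparse_rejected(self):
        with pytest.raises(ValueError, match="m=0"):
            generate_sf(target(100, 30), seed=0)

    def test_powerlaw_tail_exponent(self):
        """Preferential attachment yields a degree exponent near 3; the
        Hill/Clauset MLE over 20 graphs at N=2000, m=3 must land in
        [2.5, 3.5]."""
        alphas = []
        for seed in range(20):
            G = generate_sf(target(2000, 6000), seed=seed, m=3)
            degs = np.array([d for _, d in G.degree()])
            kmin = 3
            tail = degs[degs >= kmin]
            alpha = 1.0 + tail.size / np.sum(np.log(tail / (kmin - 0.5)))
            alphas.append(alpha)
        assert 2.5 <= np.mean(alphas) <= 3.5


class TestSFGD:
    def test_duplicate_inherits_parent_neighbours_without_divergence(self):
        """q_delete=0, p_link=0: each child's neighbour set equals its
        parent's at the moment of duplication, so one duplication of a
        degree-k node adds exactly k edges."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = generate_sf_gd(target(30, 60), seed=seed,
                               p_link=0.0, q_delete=0.0)
            # re-run the growth to verify the inheritance step directly
            H = nx.Graph()
            H.add_edge(0, 1)
            rng = np.random.default_rng(seed)
            for v in range(2, 30):
                u = int(rng.integers(v))
                inherited = list(H.neighbors(u))
                before = H.number_of_edges()
                H.add_edges_from((v, w) for w in inherited)
                rng.random()  # the p_link coin
                for _ in inherited:
                    rng.random()  # the per-neighbour divergence coins
                assert H.number_of_edges() == before + len(inherited)
                assert set(H.neighbors(v)) == set(inherited)
            assert set(G.edges()) == set(H.edges())

    def test_full_divergence_gives_tree_like_sparse_graph(self):
        """q_delete=1, p_link=0: every duplicated edge pair loses one
        member, so edges never accumulate; mean degree stays <= 2."""
        mean_degs = []
        for seed in range(50):
            G = generate_sf_gd(target(60, 100), seed=seed,
                               p_link=0.0, q_delete=1.0)
            mean_degs.append(2 * G.number_of_edges() / 60)
        assert np.mean(mean_degs) <= 2.0

    def test_calibrated_mean_edge_count_within_tolerance(self):
        from connectofit import calibrate_sf_gd
        p, q = calibrate_sf_gd(80, 200, seed=123)
        es = [generate_sf_gd(target(80, 200), seed=50000 + i,
                             p_link=p, q_delete=q).number_of_edges()
              for i in range(800)]
        # 5% calibration contract plus two standard errors of this estimate
        se = np.std(es) / math.sqrt(len(es))
        assert abs(np.mean(es) - 200) <= 0.05 * 200 + 2 * se


class TestSticky:
    def test_all_zero_degrees_give_empty_graph(self):
        G = generate_sticky(degree_target([0, 0, 0]), seed=0)
        assert G.number_of_edges() == 0

    def test_k4_pair_probability_closed_form(self):
        """For K4 degrees (all 3), theta_i*theta_j = 9/12 = 0.75; the
        empirical pair frequency over 10,000 draws must sit in
        0.75 +/- 0.02."""
        tgt = degree_target([3, 3, 3, 3])
        total_edges = sum(
            generate_sticky(tgt, seed=seed).number_of_edges()
            for seed in range(10000))
        freq = total_edges / (6 * 10000)
        assert abs(freq - 0.75) <= 0.02

    def test_expected_degrees_match_input_at_scale(self):
        """Without clipping, E[deg_i] ~ d_i; the empirical mean degree over
        200 draws at N=358 must match the input mean within 3%."""
        real = nx.gnm_random_graph(358, 3200, seed=0)
        tgt = CalibrationTarget.from_graph(real)
        mean_deg_in = 2 * tgt.n_edges / 358
        mean_degs = []
        for seed in range(200):
            G = generate_sticky(tgt, seed=seed)
            mean_degs.append(2 * G.number_of_edges() / 358)
        assert abs(np.mean(mean_degs) - mean_deg_in) / mean_deg_in <= 0.03


class TestInstances:
    def test_requested_number_of_instances(self):
        real = nx.gnm_random_graph(30, 80, seed=1)
        assert len(generate_instances(real, ModelSpec("ER", seed=0), 10)) == 10

    def test_all_instances_keep_node_count(self):
        real = nx.gnm_random_graph(30, 80, seed=1)
        for name in ("ER", "ER-DD", "GEO", "STICKY"):
            for g in generate_instances(real, ModelSpec(name, seed=2), 3):
                assert g.number_of_nodes() == 30

    def test_same_seed_reproduces_instances(self):
        real = nx.gnm_random_graph(30, 80, seed=1)
        a = generate_instances(real, ModelSpec("GEO", seed=5), 4)
        b = generate_instances(real, ModelSpec("GEO", seed=5), 4)
        assert all(set(x.edges()) == set(y.edges()) for x, y in zip(a, b))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("WATTS", seed=0)
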