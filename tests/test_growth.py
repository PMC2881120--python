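import random

import networkx as nx
import numpy as np
import pytest

from grownet.assortativity import kpartite, mixing_matrix
from grownet.distfit import rank_sum_compare
from grownet.graph_core import degree_distribution, mean_degree
from grownet.growth import (
    GrowthParams,
    callaway_pmf,
    duplicate_node,
    expected_mean_degree,
    fuse_nodes,
    grow,
    randomize_edges,
    spawn_seeds,
)


def is_simple_colored(g: nx.Graph, n_colors: int = 1) -> bool:
    no_loops = all(u != v for u, v in g.edges())
    colored = all(0 <= g.nodes[v]["color"] < n_colors for v in g)
    return no_loops and colored


class TestParams:
    @pytest.mark.parametrize("field,value", [("pn", -0.1), ("pe", 1.5), ("q", 2.0)])
    def test_probability_bounds(self, field, value):
        with pytest.raises(ValueError):
            GrowthParams(**{field: value})

    def test_color_probs_must_normalize(self):
        with pytest.raises(ValueError):
            GrowthParams(n_colors=2, color_probs=[0.7, 0.7])

    def test_e_matrix_dimension_checked(self):
        with pytest.raises(ValueError):
            GrowthParams(n_colors=3, e_matrix=kpartite(2))

    def test_eta(self):
        assert GrowthParams(pn=0.2, pe=0.75).eta == pytest.approx(3.75)
        with pytest.raises(ValueError):
            GrowthParams(pn=0.0, pe=1.0).eta


class TestGrow:
    def test_pure_node_addition_gives_isolated_nodes(self):
        g = grow(GrowthParams(pn=1.0, p=1.0, max_nodes=100), seed=0)
        assert g.number_of_nodes() == 100 and g.number_of_edges() == 0

    def test_deterministic_replay(self):
        params = GrowthParams(pn=0.3, pe=0.9, pd=0.2, q=0.8, r=0.7, max_nodes=150)
        g1, t1 = grow(params, seed=42, trace=True)
        g2, t2 = grow(params, seed=42, trace=True)
        assert nx.utils.graphs_equal(g1, g2)
        assert t1.events == t2.events

    def test_invariants_hold_for_grown_graphs(self):
        params = GrowthParams(pn=0.4, pe=0.8, pd=0.3, p=0.9, q=0.7, r=0.6,
                              n_colors=3, max_nodes=200)
        g = grow(params, seed=7)
        assert is_simple_colored(g, 3)
        d = degree_distribution(g)
        assert sum(k * c for k, c in d.counts.items()) == 2 * g.number_of_edges()

    def test_stop_by_iterations_and_edges(self):
        g = grow(GrowthParams(pn=1.0, max_iterations=57), seed=1)
        assert g.number_of_nodes() <= 58  # seed node + one per iteration
        g2 = grow(GrowthParams(pn=0.5, pe=1.0, max_edges=40), seed=1)
        assert g2.number_of_edges() >= 40

    def test_shrink_only_parameters_abort(self):
        params = GrowthParams(pn=1.0, p=0.0, max_nodes=100, iteration_cap=2000)
        with pytest.raises(RuntimeError, match="iteration cap"):
            grow(params, seed=0)

    def test_mean_degree_follows_eta(self):
        # <k> -> 2 eta for p = q = 1, no duplication
        params = GrowthParams(pn=0.2, pe=0.75, max_nodes=1000)
        ks = [mean_degree(grow(params, seed=s)) for s in spawn_seeds(3, 30)]
        assert np.mean(ks) == pytest.approx(2 * params.eta, rel=0.05)

    def test_scale_equivalence_of_event_probabilities(self):
        # halving (pn, pe) with twice the iterations leaves the degree
        # distribution statistically unchanged
        fast = GrowthParams(pn=0.6, pe=0.9, max_iterations=600)
        slow = GrowthParams(pn=0.3, pe=0.45, max_iterations=1200)
        pooled_fast, pooled_slow = [], []
        for s in spawn_seeds(11, 30):
            pooled_fast.extend(degree_distribution(grow(fast, seed=s)).degrees())
            pooled_slow.extend(degree_distribution(grow(slow, seed=s + 1)).degrees())
        assert rank_sum_compare(pooled_fast, pooled_slow) > 0.01

    def test_duplication_fattens_the_tail(self):
        # 99th-percentile degree grows with the duplication probability
        p99 = []
        for pd in (0.0, 0.25, 0.5):
            params = GrowthParams(pn=0.2, pe=0.75, pd=pd, r=1.0, max_nodes=400)
            highs = [np.percentile(degree_distribution(grow(params, seed=s)).degrees(), 99)
                     for s in spawn_seeds(17, 25)]
            p99.append(np.mean(highs))
        assert p99[0] <= p99[1] <= p99[2]

    def test_empty_initial_with_node_events_reseeds(self):
        g = grow(GrowthParams(pn=1.0, max_nodes=10), initial="empty", seed=0)
        assert g.number_of_nodes() == 10


class TestEdgeEvents:
    def test_addition_fails_on_connected_pair(self):
        # two connected nodes: a single-attempt addition can never succeed
        base = nx.Graph([(0, 1)])
        params = GrowthParams(pe=1.0, q=1.0, max_iterations=50)
        g = grow(params, initial=base, seed=5)
        assert g.number_of_edges() == 1

    def test_removal_fails_on_unconnected_pair(self):
        base = nx.empty_graph(5)
        params = GrowthParams(pe=1.0, q=0.0, max_iterations=50)
        g = grow(params, initial=base, seed=5)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 5

    def test_unlike_color_pair_never_connects_under_identity_matrix(self):
        base = nx.Graph()
        base.add_node(0, color=0)
        base.add_node(1, color=1)
        e = np.eye(2) / 2
        params = GrowthParams(pe=1.0, q=1.0, n_colors=2, e_matrix=e,
                              max_iterations=30, max_attempts=100)
        g = grow(params, initial=base, seed=2)
        assert g.number_of_edges() == 0

    def test_bipartite_matrix_yields_only_unlike_edges(self):
        params = GrowthParams(pn=0.3, pe=1.0, p=0.85, q=0.75, n_colors=2,
                              e_matrix=kpartite(2), max_iterations=1000)
        g = grow(params, initial="one-per-module", seed=9)
        assert g.number_of_edges() > 0
        assert all(g.nodes[u]["color"] != g.nodes[v]["color"] for u, v in g.edges())
        assert np.trace(mixing_matrix(g, 2)) == 0.0

    def test_failed_gated_addition_is_logged(self):
        base = nx.Graph()
        base.add_node(0, color=0)
        base.add_node(1, color=1)
        params = GrowthParams(pe=1.0, q=1.0, n_colors=2, e_matrix=np.eye(2) / 2,
                              max_iterations=5, max_attempts=10)
        _, trace = grow(params, initial=base, seed=0, trace=True)
        assert trace.counts().get("edge_add_failed", 0) == 5


class TestDuplicationAndFusion:
    def test_duplicate_isolated_node(self):
        g = nx.Graph()
        g.add_node(0, color=2)
        out = duplicate_node(g, rng=0)
        assert out.number_of_nodes() == 2 and out.number_of_edges() == 0
        assert out.nodes[1]["color"] == 2

    def test_duplicate_star_hub(self):
        # duplicating the hub doubles m (4 -> 8): two degree-4 hubs,
        # leaves at degree 2, and no hub-hub edge
        star = nx.star_graph(4)
        for seed in range(40):
            out = duplicate_node(star, rng=seed)
            if out.number_of_edges() == 8:
                degs = sorted(d for _, d in out.degree())
                assert degs == [2, 2, 2, 2, 4, 4]
                assert not out.has_edge(0, 5)
                break
        else:
            pytest.fail("hub never selected across 40 seeds")

    def test_repeated_duplication_stays_edgeless(self):
        g = nx.Graph()
        g.add_node(0, color=0)
        for seed in range(6):
            g = duplicate_node(g, rng=seed)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 7

    def test_fuse_single_edge_endpoints(self):
        out = fuse_nodes(nx.Graph([(0, 1)]), rng=0)
        assert out.number_of_nodes() == 1 and out.number_of_edges() == 0

    def test_fuse_two_hubs_discards_bridge(self):
        from grownet.modularity import two_hub_graph

        g = two_hub_graph(3)
        for seed in range(200):
            rng = random.Random(seed)
            i = rng.randrange(8)
            j = rng.randrange(7)
            if {i, (j + 1) if j >= i else j} == {0, 1}:
                out = fuse_nodes(g, rng=random.Random(seed))
                degs = sorted(d for _, d in out.degree())
                assert degs == [1, 1, 1, 1, 1, 1, 6]
                return
        pytest.fail("hub pair never selected")

    def test_fusion_merges_components(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        merged = False
        for seed in range(30):
            out = fuse_nodes(g, rng=seed)
            if nx.number_connected_components(out) == 1:
                merged = True
                assert out.number_of_nodes() == 5
                break
        assert merged


class TestAnalyticForms:
    @pytest.mark.parametrize(
        "pn,pe,q,expected",
        [(0.5, 0.5, 1.0, 2.0), (0.2, 0.75, 1.0, 7.5), (0.5, 0.0, 1.0, 0.0)],
    )
    def test_expected_mean_degree_limit(self, pn, pe, q, expected):
        assert expected_mean_degree(GrowthParams(pn=pn, pe=pe, q=q)) == pytest.approx(expected)

    def test_expected_mean_degree_requires_node_addition(self):
        with pytest.raises(ValueError, match="node addition"):
            expected_mean_degree(GrowthParams(pn=0.0, pe=1.0))

    def test_finite_size_correction_is_below_limit(self):
        params = GrowthParams(pn=0.2, pe=0.2)
        assert expected_mean_degree(params, n=2000) < expected_mean_degree(params)

    def test_callaway_pmf_normalizes_with_mean_2eta(self):
        for eta in (0.5, 1.0, 3.75):
            k = np.arange(0, 4000)
            p = callaway_pmf(k, eta)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (k * p).sum() == pytest.approx(2 * eta, rel=1e-6)


class TestRandomize:
    def test_preserves_nodes_and_rewires(self):
        g = nx.gnm_random_graph(30, 60, seed=3)
        out = randomize_edges(g, updates=300, seed=4)
        assert set(out.nodes) == set(range(30))
        assert {frozenset(e) for e in out.edges} != {frozenset(e) for e in g.edges}

    def test_edge_count_drift_matches_pair_based_dynamics(self):
        # per update E[dm] = q(1-xi) - (1-q) xi = 0.5 - xi: the walk is
        # unbiased only at half density, where m stays put on average
        n, m0 = 12, 33  # xi = 0.5 exactly (66 pairs)
        g = nx.gnm_random_graph(n, m0, seed=0)
        ms = [randomize_edges(g, updates=200, seed=s).number_of_edges()
              for s in spawn_seeds(5, 40)]
        se = np.std(ms, ddof=1) / np.sqrt(len(ms))
        assert abs(np.mean(ms) - m0) < 3 * se + 1
        # sparse graphs drift upward
        sparse = nx.gnm_random_graph(30, 20, seed=1)
        ms2 = [randomize_edges(sparse, updates=200, seed=s).number_of_edges()
               for s in spawn_seeds(6, 20)]
        assert np.mean(ms2) > 25


try:
    from hypothesis import given, settings, strategies as st

    prob = st.floats(0.0, 1.0, allow_nan=False)

    @given(pn=prob, pe=prob, pd=prob, p=prob, q=prob, r=prob,
           nc=st.integers(1, 4), seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_grown_graphs_always_satisfy_graph_invariants(pn, pe, pd, p, q, r, nc, seed):
        import warnings

        params = GrowthParams(pn=pn, pe=pe, pd=pd, p=p, q=q, r=r,
                              n_colors=nc, max_iterations=120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ending empty is legal here
            g = grow(params, initial="one-per-module", seed=seed)
        assert is_simple_colored(g, nc)
        d = degree_distribution(g)
        assert sum(k * c for k, c in d.counts.items()) == 2 * g.number_of_edges()
        assert sum(d.counts.values()) == g.number_of_nodes()
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_spawn_seeds_are_deterministic_and_bounded():
    a, b = spawn_seeds(123, 10), spawn_seeds(123, 10)
    assert a == b and len(set(a)) == 10
    assert all(0 <= s < 2**31 for s in a)
    assert spawn_seeds(124, 10) != a
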