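import numpy as np
import pytest

from entcite.netstats import (
    StatsError,
    bicomponents,
    centrality,
    compute_stats,
    degree_distributions,
    density,
    distance_stats,
    fit_power_law,
    global_clustering,
    kcore,
    top_k_table,
    weak_components,
)
from entcite.network import EntityCitationNetwork

from .conftest import eid, random_entity_digraph
from . import oracles


def net_from_pairs(pairs, isolated=()):
    return EntityCitationNetwork({p: 1 for p in pairs}, set(isolated))


def undirected(net):
    nodes = net.nodes
    edges = {tuple(sorted(((a, b)), key=lambda e: (e.entity_type.value, e.canonical_id)))
             for a, b in net.weights if a != b}
    return nodes, edges


A, B, C, D, E, F = (eid("G", x, x.lower()) for x in "ABCDEF")


class TestDensity:
    def test_complete_with_loops_is_one(self):
        pairs = [(u, v) for u in (A, B) for v in (A, B)]
        assert density(net_from_pairs(pairs)) == 1.0

    def test_three_nodes_three_arcs(self):
        assert density(net_from_pairs([(A, B), (B, C), (C, A)])) == pytest.approx(1 / 3)

    def test_empty_network_rejected(self):
        with pytest.raises(StatsError):
            density(EntityCitationNetwork({}))


class TestComponents:
    def test_two_disjoint_arcs(self):
        comps = weak_components(net_from_pairs([(A, B), (C, D)]))
        assert sorted(len(c) for c in comps) == [2, 2]

    def test_empty(self):
        assert weak_components(EntityCitationNetwork({})) == []

    def test_triangle_bicomponent(self):
        assert bicomponents(net_from_pairs([(A, B), (B, C), (C, A)])) == [{A, B, C}]

    def test_path_two_bicomponents(self):
        comps = bicomponents(net_from_pairs([(A, B), (B, C)]))
        assert sorted(sorted(e.canonical_id for e in c) for c in comps) == [
            ["A", "B"],
            ["B", "C"],
        ]


class TestKCore:
    def test_complete_k5(self):
        nodes = [A, B, C, D, E]
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        core = kcore(net_from_pairs(pairs))
        assert all(k == 4 for k in core.core_number.values())
        assert core.max_core_k == 4 and core.max_core_members == set(nodes)

    def test_star_all_core_one(self):
        leaves = [B, C, D, E, F]
        core = kcore(net_from_pairs([(A, leaf) for leaf in leaves]))
        assert set(core.core_number.values()) == {1}


class TestDistances:
    def test_path_of_three(self):
        ds = distance_stats(net_from_pairs([(A, B), (B, C)]))
        assert ds.mean_distance == pytest.approx(4 / 3)
        assert ds.diameter == 2
        assert ds.diameter_pair == (A, C)

    def test_complete_k4(self):
        nodes = [A, B, C, D]
        ds = distance_stats(net_from_pairs([(u, v) for u in nodes for v in nodes if u != v]))
        assert ds.mean_distance == 1.0 and ds.diameter == 1

    def test_single_node_rejected(self):
        with pytest.raises(StatsError):
            distance_stats(net_from_pairs([(A, A)]))

    def test_disconnected_uses_largest_component(self):
        ds = distance_stats(net_from_pairs([(A, B), (B, C), (D, E)]))
        assert ds.restricted_to_largest_component and ds.n_nodes_used == 3


class TestDegrees:
    def test_single_arc(self):
        in_h, out_h = degree_distributions(net_from_pairs([(A, B)]))
        assert in_h == {0: 1, 1: 1} and out_h == {1: 1, 0: 1}

    def test_loop_counts_once_each_way(self):
        in_h, out_h = degree_distributions(net_from_pairs([(A, A)]))
        assert in_h == {1: 1} and out_h == {1: 1}


class TestPowerLaw:
    def test_degenerate_histogram_rejected(self):
        with pytest.raises(StatsError):
            fit_power_law({3: 100})

    def test_recovers_moderate_sample(self):
        rng = np.random.default_rng(0)
        draws = rng.zipf(3.0, size=30_000)
        hist = {}
        for k in draws:
            hist[int(k)] = hist.get(int(k), 0) + 1
        fit = fit_power_law(hist)
        assert fit.gamma == pytest.approx(3.0, abs=0.15)
        assert fit.lsq_slope < 0


class TestClustering:
    def test_triangle(self):
        assert global_clustering(net_from_pairs([(A, B), (B, C), (C, A)])) == 1.0

    def test_star(self):
        assert global_clustering(net_from_pairs([(A, B), (A, C), (A, D)])) == 0.0


class TestCentrality:
    def test_path_betweenness(self):
        table = centrality(net_from_pairs([(A, B), (B, C)]), "betweenness")
        assert table.scores[B] == 1.0 and table.scores[A] == 0.0

    def test_star_center(self):
        net = net_from_pairs([(A, leaf) for leaf in (B, C, D, E)])
        assert centrality(net, "betweenness").scores[A] == 6.0  # C(4,2)
        assert centrality(net, "closeness").scores[A] == 1.0

    def test_degree_measures_on_directed_view(self):
        net = net_from_pairs([(A, B), (B, A), (A, A)])
        assert centrality(net, "in_degree").scores == {A: 2.0, B: 1.0}
        assert centrality(net, "out_degree").scores == {A: 2.0, B: 1.0}
        assert centrality(net, "degree").scores == {A: 4.0, B: 2.0}

    def test_unknown_measure(self):
        with pytest.raises(StatsError):
            centrality(net_from_pairs([(A, B)]), "pagerank")


class TestTopK:
    def test_per_type_and_combined(self):
        za, db, gc = eid("Z", "a"), eid("D", "b"), eid("G", "c")
        net = EntityCitationNetwork({(db, za): 1, (gc, za): 1, (za, db): 1})
        table = centrality(net, "in_degree")
        top = top_k_table(table, 2)
        assert [e for e, _ in top["All"]] == [za, db]
        assert len(top["DISEASE"]) == 1 and len(top["GENE"]) == 1

    def test_k_larger_than_node_count(self):
        net = net_from_pairs([(A, B)])
        top = top_k_table(centrality(net, "degree"), 50)
        assert len(top["All"]) == 2

    def test_matches_full_sort_oracle(self):
        net = random_entity_digraph(seed=7, n_max=9)
        table = centrality(net, "out_degree")
        top = top_k_table(table, 4)
        ranked = sorted(
            table.scores.items(),
            key=lambda kv: (-kv[1], kv[0].entity_type.value, kv[0].canonical_id),
        )
        assert top["All"] == ranked[:4]


@pytest.mark.parametrize("seed", range(30))
def test_metrics_match_brute_force_oracles(seed):
    """Every macro/meso/micro metric equals its independent naive oracle on a
    random directed loopful graph with <= 9 nodes."""
    net = random_entity_digraph(seed, n_max=9)
    nodes, edges = undirected(net)
    pairs = list(edges)

    assert density(net) == pytest.approx(net.m / net.n**2)

    comps = weak_components(net)
    assert sorted(map(len, comps)) == sorted(
        map(len, oracles.union_find_components(nodes, pairs))
    )
    assert {frozenset(c) for c in comps} == {
        frozenset(c) for c in oracles.union_find_components(nodes, pairs)
    }

    assert {frozenset(c) for c in bicomponents(net)} == {
        frozenset(c) for c in oracles.bicomponents_oracle(nodes, pairs)
    }

    assert kcore(net).core_number == oracles.core_numbers_oracle(nodes, pairs)

    assert global_clustering(net) == pytest.approx(
        oracles.transitivity_oracle(nodes, pairs)
    )

    in_h, out_h = degree_distributions(net)
    indeg, outdeg = oracles.degree_recount(net.weights.keys())
    from collections import Counter

    assert in_h == dict(Counter({v: indeg.get(v, 0) for v in nodes}.values()))
    assert out_h == dict(Counter({v: outdeg.get(v, 0) for v in nodes}.values()))
    assert sum(k * c for k, c in in_h.items()) == net.m
    assert sum(k * c for k, c in out_h.items()) == net.m

    if len(comps) == 1 and len(nodes) >= 2:
        mean_d, diam = oracles.mean_distance_and_diameter(nodes, pairs)
        ds = distance_stats(net)
        assert ds.mean_distance == pytest.approx(mean_d)
        assert ds.diameter == diam
        assert ds.mean_distance <= ds.diameter

        close = centrality(net, "closeness").scores
        for v, expected in oracles.closeness_oracle(nodes, pairs).items():
            assert close[v] == pytest.approx(expected)

        btw = centrality(net, "betweenness").scores
        for v, expected in oracles.betweenness_oracle(nodes, pairs).items():
            assert btw[v] == pytest.approx(expected)


def test_compute_stats_is_consistent():
    net = random_entity_digraph(seed=3, n_max=9)
    gs = compute_stats(net)
    assert gs.n == net.n and gs.m == net.m
    assert 0 <= gs.clustering <= 1
    assert sum(gs.component_sizes) == net.n
    d = gs.to_dict()
    import json

    json.dumps(d)  # JSON-serializable report
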