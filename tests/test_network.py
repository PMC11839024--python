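"""Network integration: construction, filters, stats, communities,
rewiring nulls, coherence, triangles, compartment tabulation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from endonet import network


def _edges(pairs, **kw):
    rows = [{"accession_a": a, "accession_b": b, **kw} for a, b in pairs]
    return pd.DataFrame(rows)


def brute_force_triangles(g, require_xl=True):
    out = []
    for a, b, c in itertools.combinations(sorted(g.nodes, key=str), 3):
        if g.has_edge(a, b) and g.has_edge(a, c) and g.has_edge(b, c):
            if require_xl and not any(
                g[u][v].get("xl_count", 0) >= 1
                for u, v in ((a, b), (a, c), (b, c))
            ):
                continue
            out.append((a, b, c))
    return out


class TestBuild:
    def test_merged_evidence_single_edge(self):
        g = network.build_network(
            _edges([("A", "B")], xl_count=2),
            _edges([("A", "B")], bn_replicates_passing=3),
        )
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["xl_count"] == 2
        assert g["A"]["B"]["bn_replicates_passing"] == 3

    def test_blocklist_and_keratins_removed(self):
        g = network.build_network(
            _edges([("UBC", "A"), ("KRT18", "B"), ("A", "B")], xl_count=1),
            None,
        )
        assert "UBC" not in g and "KRT18" not in g
        assert g.has_edge("A", "B")

    def test_empty_inputs(self):
        g = network.build_network(None, None)
        assert g.number_of_nodes() == 0


class TestEndosomeCenter:
    def _graph(self):
        # E endosomal; D direct interactor; S1/S2/S3 second-order
        xl = _edges([("E", "D"), ("D", "S1")], xl_count=1)
        bn = _edges(
            [("D", "S2"), ("D2", "S2"), ("D", "S3")],
            bn_replicates_passing=2,
        )
        xl2 = _edges([("E", "D2")], xl_count=1)
        g = network.build_network(pd.concat([xl, xl2]), bn)
        return g

    def test_xl_supported_second_order_retained(self):
        g = network.endosome_center_filter(self._graph(), {"E"})
        assert "S1" in g

    def test_bn_two_direct_retained_one_dropped(self):
        g = network.endosome_center_filter(self._graph(), {"E"})
        assert "S2" in g  # BN edges to two direct interactors (D and D2)
        assert "S3" not in g  # single BN edge only

    def test_nuclear_nodes_removed(self):
        g = network.endosome_center_filter(
            self._graph(), {"E"}, nuclear={"S1"}
        )
        assert "S1" not in g

    def test_empty_endosomal_rejected(self):
        with pytest.raises(ValueError):
            network.endosome_center_filter(self._graph(), set())

    def test_filter_order_independence(self):
        """blocklist-then-center equals center-then-blocklist."""
        xl = _edges(
            [("E", "D"), ("D", "S1"), ("E", "UBC"), ("UBC", "S1")],
            xl_count=1,
        )
        g_blocked = network.build_network(xl, None)  # blocklist applied
        a = network.endosome_center_filter(g_blocked, {"E"})
        g_raw = network.build_network(xl, None, blocklist=())
        b = network.endosome_center_filter(g_raw, {"E"})
        b.remove_nodes_from([n for n in list(b) if n == "UBC"])
        assert set(a.nodes) == set(b.nodes)
        assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))


class TestCoreComponent:
    def test_larger_component_wins(self):
        g = nx.Graph()
        nx.add_path(g, [1, 2, 3, 4, 5])
        nx.add_path(g, [10, 11, 12])
        assert set(network.core_component(g)) == {1, 2, 3, 4, 5}

    def test_connected_graph_is_itself(self):
        g = nx.complete_graph(4)
        assert set(network.core_component(g)) == set(g)

    def test_tie_broken_by_edge_count(self):
        g = nx.Graph()
        g.add_edges_from([(1, 2), (2, 3), (3, 4), (4, 1), (1, 3)])  # 4n 5e
        nx.add_path(g, [10, 11, 12, 13])  # 4 nodes 3 edges
        assert set(network.core_component(g)) == {1, 2, 3, 4}

    def test_empty_graph(self):
        assert network.core_component(nx.Graph()).number_of_nodes() == 0


class TestStats:
    def test_path_graph_mean_shortest_path(self):
        g = nx.path_graph(3)
        # pairs (0,1)=1 (1,2)=1 (0,2)=2 -> mean 4/3
        assert network.mean_shortest_path(g) == pytest.approx(4 / 3)

    def test_complete_graph_mean_one(self):
        assert network.mean_shortest_path(nx.complete_graph(5)) == 1.0

    def test_perfect_powerlaw_histogram(self):
        # degree counts 4x1, 2x2, 1x4: frequency halves as degree doubles,
        # exactly log-log linear
        g = nx.havel_hakimi_graph([4, 2, 2, 1, 1, 1, 1])
        assert network.powerlaw_r2(g) == pytest.approx(1.0, abs=1e-9)

    def test_tiny_graph_flagged(self):
        assert network.network_stats(nx.Graph())["degenerate"]

    def test_scale_free_vs_random(self):
        """Preferential-attachment degree distributions fit a power law
        markedly better than same-size random graphs, for every seed."""
        for seed in range(5):
            ba = nx.barabasi_albert_graph(2000, 2, seed=seed)
            er = nx.gnp_random_graph(2000, 4 / 1999, seed=seed)
            ba_r2 = network.powerlaw_r2(ba)
            er_r2 = network.powerlaw_r2(er)
            assert ba_r2 > 0.75
            assert ba_r2 > er_r2 + 0.2


class TestCommunities:
    def test_two_triangles_bridge(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z"),
                          ("c", "x")])
        parts = network.detect_communities(g)
        # brute-force: best modularity 2-cut is the two triangles
        best_q, best_cut = -1, None
        nodes = sorted(g.nodes)
        for r in range(1, len(nodes) // 2 + 1):
            for left in itertools.combinations(nodes, r):
                cut = [set(left), set(nodes) - set(left)]
                q = nx.community.modularity(g, cut)
                if q > best_q:
                    best_q, best_cut = q, cut
        assert len(parts) == 2
        assert {frozenset(p) for p in parts} == \
            {frozenset(c) for c in best_cut}

    def test_complete_graph_one_community(self):
        parts = network.detect_communities(nx.complete_graph(5))
        assert len(parts) == 1

    def test_disconnected_partitioned_independently(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        parts = network.detect_communities(g)
        assert {frozenset(p) for p in parts} == \
            {frozenset({"a", "b"}), frozenset({"c", "d"})}


class TestRewire:
    def test_degree_sequence_conserved(self):
        g = nx.barabasi_albert_graph(60, 2, seed=1)
        nulls = network.rewire_null(g, n_permutations=10, seed=5)
        deg = sorted(d for _, d in g.degree())
        for h in nulls:
            assert sorted(d for _, d in h.degree()) == deg
            assert not any(u == v for u, v in h.edges)

    def test_four_cycle_persists(self):
        # the only degree-preserving simple graph on C4's degree sequence
        # reachable by double swaps is C4 itself
        g = nx.cycle_graph(4)
        for h in network.rewire_null(g, n_permutations=5, seed=0):
            assert sorted(d for _, d in h.degree()) == [2, 2, 2, 2]
            assert nx.is_isomorphic(h, g)

    def test_seeded_reproducibility(self):
        g = nx.barabasi_albert_graph(40, 2, seed=2)
        a = network.rewire_null(g, n_permutations=3, seed=9)
        b = network.rewire_null(g, n_permutations=3, seed=9)
        for ha, hb in zip(a, b):
            assert set(map(frozenset, ha.edges)) == \
                set(map(frozenset, hb.edges))

    def test_star_returned_unchanged(self):
        g = nx.star_graph(4)
        with pytest.warns(UserWarning):
            nulls = network.rewire_null(nx.Graph([(0, 1)]),
                                        n_permutations=2, seed=0)
        assert all(set(h.edges) == {(0, 1)} for h in nulls)
        nulls = network.rewire_null(g, n_permutations=2, seed=0)
        assert all(sorted(d for _, d in h.degree()) == [1, 1, 1, 1, 4]
                   for h in nulls)


class TestCoherence:
    def test_clique_complex_distance_one(self):
        g = nx.complete_graph(["a", "b", "c"])
        nx.add_path(g, ["c", "x", "y", "z"])
        res = network.complex_coherence(g, {"cpx": ["a", "b", "c"]})
        assert res["within_distances"] == [1, 1, 1]

    def test_random_labels_not_enriched(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(60, 0.1, seed=1)
        labels = {f"cpx{i}": list(rng.choice(60, size=5, replace=False))
                  for i in range(4)}
        nulls = network.rewire_null(g, n_permutations=30, seed=2)
        res = network.complex_coherence(g, labels, nulls)
        # permutation oracle: random labels should not beat the null
        assert res["empirical_p"] > 0.05

    def test_empirical_p_lower_bound(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        nulls = network.rewire_null(g, n_permutations=100, seed=0)
        res = network.complex_coherence(g, {"cpx": ["a", "b"]}, nulls)
        assert res["empirical_p"] >= 1 / 101

    def test_single_member_complex_skipped(self):
        g = nx.path_graph(["a", "b", "c"])
        res = network.complex_coherence(g, {"cpx": ["a"]})
        assert res["within_distances"] == []


class TestTriangles:
    def test_bn_only_triangle_excluded(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, xl_count=0, bn_replicates_passing=2)
        assert network.enumerate_3cliques(g) == []

    def test_one_xl_edge_included(self):
        g = nx.Graph()
        g.add_edge("a", "b", xl_count=1)
        g.add_edge("b", "c", xl_count=0)
        g.add_edge("a", "c", xl_count=0)
        assert network.enumerate_3cliques(g) == [("a", "b", "c")]

    def test_k4_all_xl(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        nx.set_edge_attributes(g, 1, "xl_count")
        tris = network.enumerate_3cliques(g)
        assert len(tris) == 4
        assert tris == brute_force_triangles(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(30, 0.2, seed=seed)
        for u, v in g.edges:
            g[u][v]["xl_count"] = int(rng.random() < 0.5)
        assert network.enumerate_3cliques(g) == brute_force_triangles(g)


class TestCompartments:
    def test_all_endosomal(self):
        g = nx.complete_graph(["a", "b", "c"])
        comp = {n: ["endosome"] for n in g}
        res = network.compartment_connectivity(g, comp)
        assert res["fraction_endo_lyso_golgi"] == 1.0

    def test_nuclear_star(self):
        g = nx.star_graph(["hub", "n1", "n2", "n3"])
        comp = {"hub": ["endosome"], "n1": ["nucleus"], "n2": ["nucleus"],
                "n3": ["nucleus"]}
        res = network.compartment_connectivity(g, comp)
        assert res["fraction_endo_lyso_golgi"] == 0.0

    def test_hand_tabulated_mixed_graph(self):
        g = nx.Graph()
        comp = {
            "e1": ["endosome"], "e2": ["endosome"], "l1": ["lysosome"],
            "g1": ["golgi"], "m1": ["mito"], "n1": ["nucleus"],
            "el": ["endosome", "lysosome"],  # precedence -> endosome
        }
        edges = [("e1", "e2"), ("e1", "l1"), ("e1", "g1"), ("e2", "m1"),
                 ("e2", "n1"), ("e1", "el"), ("l1", "g1")]
        g.add_edges_from(edges)
        res = network.compartment_connectivity(g, comp)
        # endosome-incident edges: all but (l1,g1) -> 6; partners in
        # {endo,lyso,golgi}: e1-e2, e1-l1, e1-g1, e1-el -> 4
        assert res["n_endosomal_edges"] == 6
        assert res["fraction_endo_lyso_golgi"] == pytest.approx(4 / 6)
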