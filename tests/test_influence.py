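"""Influence scoring: hand examples, enumeration oracle, invariants."""

from __future__ import annotations

import networkx as nx
import pytest

import mirconverge as mc
from mirconverge.datatypes import ValidationError

from conftest import make_mti, make_signature
from test_network import net_from


def oracle_influence(graph, mirna, scores, alpha, max_len):
    """Independent route: per-pair simple-path enumeration via networkx."""
    total = 0.0
    for gene, s in scores.items():
        if gene not in graph:
            continue
        for path in nx.all_simple_paths(graph, mirna, gene, cutoff=max_len):
            total += s * alpha ** (len(path) - 1)
    return total


def random_influence_graph(rng, n_genes, n_mirnas=2, p_gene=0.25, p_mirna=0.5):
    graph = nx.DiGraph()
    genes = [f"G{i}" for i in range(n_genes)]
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    graph.add_nodes_from(genes, kind="gene")
    graph.add_nodes_from(mirnas, kind="mirna")
    for a in genes:
        for b in genes:
            if a != b and rng.random() < p_gene:
                graph.add_edge(a, b)
    for m in mirnas:
        for g in genes:
            if rng.random() < p_mirna:
                graph.add_edge(m, g)
    scores = {g: float(rng.integers(0, 12)) for g in genes}
    return graph, mirnas, scores


class TestGraphConstruction:
    def test_node_and_edge_counts(self):
        sig = make_signature(high=["m1", "m2"])
        mti = make_mti([("m1", "A"), ("m1", "ZZZ-outside"), ("m2", "B")])
        net = net_from(edges=[("A", "B", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        assert set(graph.nodes) == {"m1", "m2", "A", "B"}
        assert set(graph.edges) == {("m1", "A"), ("m2", "B"), ("A", "B")}

    def test_mirna_with_no_in_network_target_is_isolated(self):
        sig = make_signature(high=["m1"])
        mti = make_mti([("m1", "OUTSIDE")])
        net = net_from(edges=[("A", "B", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        assert graph.degree("m1") == 0

    def test_no_edges_into_mirna_nodes(self, rng):
        sig = make_signature(high=["m1", "m2"])
        mti = make_mti([("m1", "A"), ("m2", "B")])
        net = net_from(edges=[("A", "B", "activation"),
                              ("B", "A", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        for m in ("m1", "m2"):
            assert graph.in_degree(m) == 0


class TestEnumerateSimplePaths:
    def test_direct_edge_single_path(self):
        graph = nx.DiGraph([("m", "g")])
        assert mc.enumerate_simple_paths(graph, "m", "g", 5) == \
            [(["m", "g"], 1)]

    def test_diamond_two_paths_of_length_two(self):
        graph = nx.DiGraph([("m", "g1"), ("m", "g2"),
                            ("g1", "g3"), ("g2", "g3")])
        paths = mc.enumerate_simple_paths(graph, "m", "g3", 5)
        assert sorted(length for _, length in paths) == [2, 2]

    def test_cap_excludes_longer_paths(self):
        graph = nx.DiGraph([("m", "a"), ("a", "b"), ("b", "g"), ("m", "g")])
        lengths = sorted(
            l for _, l in mc.enumerate_simple_paths(graph, "m", "g", 2)
        )
        assert lengths == [1]

    def test_matches_recursive_enumeration_on_random_dags(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            nodes = list(range(n))
            graph = nx.DiGraph()
            graph.add_nodes_from(nodes)
            for i in nodes:
                for j in nodes:
                    if i < j and rng.random() < 0.3:
                        graph.add_edge(i, j)

            def brute(node, target, visited):
                if node == target:
                    return [[node]]
                out = []
                for nxt in graph.successors(node):
                    if nxt not in visited:
                        for tail in brute(nxt, target, visited | {nxt}):
                            out.append([node] + tail)
                return out

            src, tgt = 0, n - 1
            want = sorted(p for p in brute(src, tgt, {src}) if len(p) - 1 <= 6)
            got = sorted(p for p, _ in
                         mc.enumerate_simple_paths(graph, src, tgt, 6))
            assert got == want


class TestInfluenceScore:
    def test_single_direct_target(self):
        graph = nx.DiGraph([("m", "g")])
        assert mc.influence_score("m", graph, {"g": 10.0}) == \
            pytest.approx(1.0, abs=1e-12)

    def test_two_gene_chain(self):
        graph = nx.DiGraph([("m", "g1"), ("g1", "g2")])
        got = mc.influence_score("m", graph, {"g1": 5.0, "g2": 10.0})
        assert got == pytest.approx(0.6, abs=1e-12)

    def test_two_paths_to_one_gene(self):
        graph = nx.DiGraph([("m", "g"), ("m", "h"), ("h", "g")])
        got = mc.influence_score("m", graph, {"g": 1.0, "h": 0.0})
        assert got == pytest.approx(0.11, abs=1e-12)

    def test_missing_mirna_errors(self):
        with pytest.raises(ValidationError, match="not in the influence"):
            mc.influence_score("nope", nx.DiGraph(), {})

    def test_oracle_equivalence_on_random_graphs(self, rng):
        for _ in range(20):
            graph, mirnas, scores = random_influence_graph(
                rng, n_genes=int(rng.integers(3, 10))
            )
            for m in mirnas:
                want = oracle_influence(graph, m, scores, 0.1, 6)
                got = mc.influence_score(m, graph, scores, alpha=0.1,
                                         max_len=6)
                assert got == pytest.approx(want, abs=1e-12)

    def test_additivity_over_disconnected_components(self):
        graph = nx.DiGraph([("m", "a1"), ("a1", "a2"),
                            ("m", "b1"), ("b1", "b2")])
        scores = {"a1": 3.0, "a2": 7.0, "b1": 2.0, "b2": 5.0}
        whole = mc.influence_score("m", graph, scores)
        part_a = mc.influence_score("m", graph, {k: scores[k]
                                                 for k in ("a1", "a2")})
        part_b = mc.influence_score("m", graph, {k: scores[k]
                                                 for k in ("b1", "b2")})
        assert whole == pytest.approx(part_a + part_b, abs=1e-12)

    def test_monotone_in_max_len_and_alpha(self, rng):
        graph, mirnas, scores = random_influence_graph(rng, n_genes=7)
        m = mirnas[0]
        by_len = [mc.influence_score(m, graph, scores, max_len=L)
                  for L in (1, 2, 4, 8)]
        assert all(a <= b + 1e-15 for a, b in zip(by_len, by_len[1:]))
        by_alpha = [mc.influence_score(m, graph, scores, alpha=a)
                    for a in (0.05, 0.1, 0.3)]
        if by_alpha[0] > 0:
            assert by_alpha[0] < by_alpha[1] < by_alpha[2]

    def test_truncation_bound_between_consecutive_caps(self, rng):
        graph, mirnas, scores = random_influence_graph(rng, n_genes=8)
        m = mirnas[0]
        alpha, L = 0.1, 3
        lo = mc.influence_score(m, graph, scores, alpha=alpha, max_len=L)
        hi = mc.influence_score(m, graph, scores, alpha=alpha, max_len=L + 1)
        n_new = sum(
            1
            for g in scores
            if g in graph
            for p in nx.all_simple_paths(graph, m, g, cutoff=L + 1)
            if len(p) - 1 == L + 1
        )
        bound = n_new * alpha ** (L + 1) * max(scores.values())
        assert 0 <= hi - lo <= bound + 1e-12


class TestRankMirnas:
    def test_all_zero_scores_give_zero_influence(self):
        sig = make_signature(high=["m1", "m2"])
        mti = make_mti([("m1", "A"), ("m2", "A")])
        net = net_from(edges=[("A", "B", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        res = mc.rank_mirnas(sig, graph, {"A": 0.0, "B": 0.0})
        assert res.table["influence"].tolist() == [0.0, 0.0]

    def test_identical_target_sets_identical_influence(self):
        sig = make_signature(high=["m1", "m2"])
        mti = make_mti([("m1", "A"), ("m2", "A")])
        net = net_from(edges=[("A", "B", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        res = mc.rank_mirnas(sig, graph, {"A": 4.0, "B": 2.0})
        vals = res.influences
        assert vals["m1"] == pytest.approx(vals["m2"], abs=1e-15)

    def test_deleting_only_edge_zeroes_one_mirna_only(self):
        sig = make_signature(high=["m1", "m2"])
        mti_full = make_mti([("m1", "A"), ("m2", "B")])
        mti_cut = make_mti([("m2", "B")])
        net = net_from(edges=[("B", "C", "activation"),
                              ("A", "D", "activation")])
        scores = {"A": 3.0, "B": 2.0, "C": 1.0, "D": 1.0}
        full = mc.rank_mirnas(
            sig, mc.build_influence_graph(sig, mti_full, net), scores
        ).influences
        cut = mc.rank_mirnas(
            sig, mc.build_influence_graph(sig, mti_cut, net), scores
        ).influences
        assert cut["m1"] == 0.0
        assert cut["m2"] == pytest.approx(full["m2"], abs=1e-15)

    def test_sorted_descending_with_lexicographic_ties(self):
        sig = make_signature(high=["mB", "mA"])
        mti = make_mti([("mA", "A"), ("mB", "A")])
        net = net_from(edges=[("A", "B", "activation")])
        graph = mc.build_influence_graph(sig, mti, net)
        res = mc.rank_mirnas(sig, graph, {"A": 1.0, "B": 1.0})
        assert res.table["mirna_id"].tolist() == ["mA", "mB"]
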