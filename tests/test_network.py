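"""Network curation and Katz centrality: rules, oracles, invariants."""

from __future__ import annotations

import numpy as np
import pytest

import mirconverge as mc
from mirconverge.datatypes import (
    AnnotationConflictError,
    DirectedEdge,
    DirectedInteractionNetwork,
    PendingInteraction,
    ValidationError,
)

from conftest import make_ppi


def net_from(edges=(), pending=()):
    return DirectedInteractionNetwork(
        edges={(s, t): DirectedEdge(sign=sign) for s, t, sign in edges},
        pending=tuple(
            PendingInteraction(a, b, kind, sign) for a, b, kind, sign in pending
        ),
    )


def random_net(rng, n_nodes, p_edge=0.25, sign="activation"):
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = [
        (a, b, sign)
        for a in nodes for b in nodes
        if a != b and rng.random() < p_edge
    ]
    return net_from(edges)


class TestTrimming:
    def test_rule_application(self):
        net = net_from(
            edges=[("C", "D", "activation")],
            pending=[("A", "B", "undirected", "activation"),
                     ("E", "F", "bidirectional", "inhibition")],
        )
        out = mc.trim_to_directed(net)
        assert set(out.edges) == {("C", "D"), ("E", "F"), ("F", "E")}
        assert out.edges[("E", "F")].sign == "inhibition"
        assert out.pending == ()

    def test_all_undirected_becomes_empty(self):
        net = net_from(pending=[("A", "B", "undirected", "activation")])
        assert mc.trim_to_directed(net).n_edges == 0

    def test_edge_count_conservation_randomized(self, rng):
        for _ in range(20):
            n_dir = int(rng.integers(0, 15))
            n_bi = int(rng.integers(0, 10))
            n_und = int(rng.integers(0, 10))
            edges, pending, label = [], [], 0
            for _ in range(n_dir):
                edges.append((f"a{label}", f"b{label}", "activation"))
                label += 1
            for _ in range(n_bi):
                pending.append((f"a{label}", f"b{label}", "bidirectional",
                                "activation"))
                label += 1
            for _ in range(n_und):
                pending.append((f"a{label}", f"b{label}", "undirected",
                                "inhibition"))
                label += 1
            out = mc.trim_to_directed(net_from(edges, pending))
            assert out.n_edges == n_dir + 2 * n_bi


class TestMissingConnections:
    def test_existing_edge_not_reported(self):
        net = net_from(edges=[("A", "B", "activation")])
        ppi = make_ppi([("A", "B", 0.96)])
        assert mc.find_missing_connections(net, ppi, 0.95) == []

    def test_reverse_edge_also_counts_as_present(self):
        net = net_from(edges=[("B", "A", "activation")])
        ppi = make_ppi([("A", "B", 0.96)])
        assert mc.find_missing_connections(net, ppi, 0.95) == []

    def test_absent_pair_reported(self):
        net = net_from(edges=[("A", "C", "activation"),
                              ("B", "C", "activation")])
        ppi = make_ppi([("A", "B", 0.96)])
        assert mc.find_missing_connections(net, ppi, 0.95) == [("A", "B")]

    def test_threshold_boundary_is_inclusive(self):
        net = net_from(edges=[("A", "C", "activation"),
                              ("B", "C", "activation")])
        assert mc.find_missing_connections(
            net, make_ppi([("A", "B", 0.94)]), 0.95) == []
        assert mc.find_missing_connections(
            net, make_ppi([("A", "B", 0.95)]), 0.95) == [("A", "B")]


class TestAnnotations:
    def base(self):
        return net_from(edges=[("X", "Y", "activation")])

    def test_one_directional_annotation_adds_edge(self):
        ann = mc.AnnotationTable(
            rows=(mc.AnnotationRow("A", "B", "a_to_b", "activation", "PMID:1"),)
        )
        out = mc.apply_annotations(self.base(), ann)
        assert out.edges[("A", "B")].sign == "activation"

    def test_none_direction_changes_nothing(self):
        ann = mc.AnnotationTable(
            rows=(mc.AnnotationRow("A", "B", "none", "unknown"),)
        )
        out = mc.apply_annotations(self.base(), ann)
        assert set(out.edges) == {("X", "Y")}

    def test_both_adds_two_edges(self):
        ann = mc.AnnotationTable(
            rows=(mc.AnnotationRow("A", "B", "both", "inhibition"),)
        )
        out = mc.apply_annotations(self.base(), ann)
        assert out.edges[("A", "B")].sign == "inhibition"
        assert out.edges[("B", "A")].sign == "inhibition"

    def test_conflicting_sign_is_hard_error(self):
        ann = mc.AnnotationTable(
            rows=(mc.AnnotationRow("X", "Y", "a_to_b", "inhibition"),)
        )
        with pytest.raises(AnnotationConflictError):
            mc.apply_annotations(self.base(), ann)

    def test_agreeing_annotation_never_overwrites(self):
        ann = mc.AnnotationTable(
            rows=(mc.AnnotationRow("X", "Y", "a_to_b", "activation", "new"),)
        )
        out = mc.apply_annotations(self.base(), ann)
        assert out.edges[("X", "Y")].provenance == ""  # original kept


class TestFilterActivating:
    def test_mixed_signs_keep_activation_only(self):
        net = net_from(edges=[("A", "B", "activation"),
                              ("B", "C", "inhibition"),
                              ("C", "D", "unknown")])
        out = mc.filter_activating(net)
        assert set(out.edges) == {("A", "B")}

    def test_all_inhibition_becomes_empty(self):
        net = net_from(edges=[("A", "B", "inhibition")])
        assert mc.filter_activating(net).n_edges == 0

    def test_idempotent(self, rng):
        net = random_net(rng, 8)
        once = mc.filter_activating(net)
        twice = mc.filter_activating(once)
        assert dict(once.edges) == dict(twice.edges)


# ---------------------------------------------------------------------------
# Katz centrality
# ---------------------------------------------------------------------------

def truncated_series_katz(net, nodes, alpha, beta, n_terms=40):
    """Independent oracle: beta * sum_k alpha^k (walk counts into each node)."""
    node_list = sorted(set(net.nodes) | set(nodes))
    index = {g: i for i, g in enumerate(node_list)}
    n = len(node_list)
    A = np.zeros((n, n))
    for (s, t) in net.edges:
        A[index[s], index[t]] = 1.0
    x = np.full(n, float(beta))
    walk = np.full(n, float(beta))
    for _ in range(n_terms):
        walk = alpha * (A.T @ walk)
        x = x + walk
    return dict(zip(node_list, x))


class TestKatz:
    def test_edgeless_graph_gives_all_beta(self):
        table = mc.katz_centrality(net_from(), nodes=[f"N{i}" for i in range(5)])
        assert np.allclose(table.table["katz"], 1.0)

    def test_chain_recursion(self):
        net = net_from(edges=[("A", "B", "activation"),
                              ("B", "C", "activation")])
        katz = mc.katz_centrality(net, alpha=0.1, beta=1.0).katz
        assert katz["A"] == pytest.approx(1.0, abs=1e-12)
        assert katz["B"] == pytest.approx(1.1, abs=1e-12)
        assert katz["C"] == pytest.approx(1.11, abs=1e-12)

    def test_two_cycle_closed_form(self):
        net = net_from(edges=[("A", "B", "activation"),
                              ("B", "A", "activation")])
        katz = mc.katz_centrality(net, alpha=0.1, beta=1.0).katz
        assert katz["A"] == pytest.approx(1.1 / 0.99, abs=1e-12)
        assert katz["B"] == pytest.approx(1.1 / 0.99, abs=1e-12)

    def test_linear_solve_matches_truncated_series(self, rng):
        for _ in range(25):
            net = random_net(rng, int(rng.integers(2, 16)), p_edge=0.2)
            nodes = set(net.nodes) | {"ISO"}
            got = mc.katz_centrality(net, alpha=0.1, beta=1.0,
                                     nodes=nodes).katz
            want = truncated_series_katz(net, nodes, 0.1, 1.0)
            for g in want:
                assert got[g] == pytest.approx(want[g], abs=1e-9)

    def test_matches_networkx_unnormalized(self, rng):
        import networkx as nx

        net = random_net(rng, 10, p_edge=0.25)
        if not net.edges:
            pytest.skip("empty random draw")
        G = nx.DiGraph(list(net.edges))
        ref = nx.katz_centrality_numpy(G, alpha=0.1, beta=1.0,
                                       normalized=False)
        got = mc.katz_centrality(net, alpha=0.1, beta=1.0).katz
        for g, v in ref.items():
            assert got[g] == pytest.approx(v, abs=1e-9)

    def test_incoming_edge_monotonicity(self, rng):
        net = random_net(rng, 8, p_edge=0.2)
        nodes = sorted(net.nodes) or ["N0", "N1"]
        target = nodes[0]
        new_src = "EXTRA"
        before = mc.katz_centrality(net, nodes=[new_src]).katz[target]
        edges = dict(net.edges)
        edges[(new_src, target)] = DirectedEdge(sign="activation")
        bigger = DirectedInteractionNetwork(edges=edges)
        after = mc.katz_centrality(bigger).katz[target]
        assert after >= before

    def test_label_invariance(self, rng):
        net = random_net(rng, 9, p_edge=0.25)
        mapping = {n: f"Z{n}" for n in net.nodes}
        relabeled = DirectedInteractionNetwork(edges={
            (mapping[s], mapping[t]): e for (s, t), e in net.edges.items()
        })
        orig = mc.katz_centrality(net).katz
        perm = mc.katz_centrality(relabeled).katz
        for n, v in orig.items():
            assert perm[mapping[n]] == pytest.approx(v, abs=1e-12)

    def test_alpha_beyond_convergence_bound_reports_radius(self):
        net = net_from(edges=[("A", "B", "activation"),
                              ("B", "A", "activation")])  # radius 1
        with pytest.raises(ValidationError, match="spectral"):
            mc.katz_centrality(net, alpha=1.0)


class TestCombinedScores:
    def test_zero_frequency_gives_zero_combined(self):
        net = net_from(edges=[("A", "B", "activation")])
        katz = mc.katz_centrality(net)
        out = mc.combined_scores(katz, {"A": 0, "B": 5})
        combined = out.combined
        assert combined["A"] == 0.0
        assert combined["B"] == pytest.approx(1.1 * 5)

    def test_edgeless_ranking_equals_frequency_ranking(self):
        katz = mc.katz_centrality(net_from(), nodes=["A", "B", "C"])
        out = mc.combined_scores(katz, {"A": 2, "B": 7, "C": 5})
        assert out.table["gene"].tolist() == ["B", "C", "A"]

    def test_missing_gene_is_hard_error(self):
        katz = mc.katz_centrality(net_from(), nodes=["A", "B"])
        with pytest.raises(ValidationError, match="missing"):
            mc.combined_scores(katz, {"A": 1})

    def test_elementwise_product_recomputed(self, rng):
        net = random_net(rng, 7, p_edge=0.3)
        nodes = sorted(set(net.nodes) | {"LONER"})
        freq = {g: int(rng.integers(0, 9)) for g in nodes}
        katz = mc.katz_centrality(net, nodes=nodes)
        out = mc.combined_scores(katz, freq)
        for row in out.table.itertuples():
            assert row.combined == pytest.approx(
                katz.katz[row.gene] * freq[row.gene], abs=1e-12
            )
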