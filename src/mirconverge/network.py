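"""Directed-network curation and Katz-centrality combined scores.

The curation chain mirrors how a signed functional-interaction network is
prepared for centrality analysis: drop undirected edges, split
bidirectional ones into two opposite directed edges, cross-reference the
result against a high-confidence PPI network to surface missing pairs,
fold in manually curated direction/sign calls, and finally keep only
unambiguous activating edges. Katz centrality (incoming-edge convention,
x_v = beta + alpha * sum over incoming neighbors of x_u) is solved exactly
as a dense linear system after checking the spectral-radius convergence
condition; each gene's centrality times its targeting-frequency score is
its final combined score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationConflictError,
    AnnotationTable,
    DirectedEdge,
    DirectedInteractionNetwork,
    UndirectedPPINetwork,
    ValidationError,
    canonical_pair,
)
from .scoring import GeneScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityTable",
    "trim_to_directed",
    "find_missing_connections",
    "apply_annotations",
    "filter_activating",
    "katz_centrality",
    "combined_scores",
]


@dataclass(frozen=True)
class CentralityTable:
    """Katz centralities and combined (katz x frequency) gene scores.

    ``table`` columns: gene, katz and — once :func:`combined_scores` has
    run — frequency_score and combined. A node with no incoming edges has
    katz exactly beta.
    """

    table: pd.DataFrame
    alpha: float
    beta: float

    @property
    def katz(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["katz"]))

    @property
    def combined(self) -> dict[str, float]:
        if "combined" not in self.table.columns:
            raise ValidationError(
                "combined scores not computed yet; call combined_scores()"
            )
        return dict(zip(self.table["gene"], self.table["combined"]))

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def trim_to_directed(
    net: DirectedInteractionNetwork,
) -> DirectedInteractionNetwork:
    """Drop undirected interactions; split bidirectional ones into two edges.

    Output edge count = (directed in) + 2 x (bidirectional in), provided
    the split edges do not collide with existing ordered pairs (a
    collision is an input inconsistency and raises).
    """
    edges = dict(net.edges)
    for p in net.pending:
        if p.kind == "undirected":
            continue
        for src, tgt in ((p.gene_a, p.gene_b), (p.gene_b, p.gene_a)):
            if (src, tgt) in edges:
                raise ValidationError(
                    f"bidirectional split of ({p.gene_a!r}, {p.gene_b!r}) "
                    f"collides with an existing {src!r}->{tgt!r} edge"
                )
            edges[(src, tgt)] = DirectedEdge(sign=p.sign,
                                             provenance=p.provenance)
    return DirectedInteractionNetwork(edges=edges, pending=())


def find_missing_connections(
    net: DirectedInteractionNetwork,
    ppi: UndirectedPPINetwork,
    threshold: float = 0.95,
) -> list[tuple[str, str]]:
    """High-confidence PPI pairs absent from the directed network.

    Returns canonical unordered pairs of ``net``'s nodes with PPI
    confidence >= threshold and no directed edge in either direction —
    the candidates for manual direction/sign curation.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    node_set = set(net.nodes)
    missing = [
        (a, b)
        for (a, b), conf in ppi.edges.items()
        if conf >= threshold
        and a in node_set
        and b in node_set
        and not net.has_any_edge(a, b)
    ]
    return sorted(missing)


def apply_annotations(
    net: DirectedInteractionNetwork, ann: AnnotationTable
) -> DirectedInteractionNetwork:
    """Add manually curated directed signed edges.

    ``a_to_b``/``b_to_a`` add one edge, ``both`` adds two, ``none`` adds
    nothing. Existing edges are never overwritten: an annotation agreeing
    with an existing edge's sign is a no-op, a disagreeing one is a hard
    error.
    """
    edges = dict(net.edges)
    for row in ann.rows:
        if row.resolved_direction == "none":
            continue
        if row.resolved_direction == "a_to_b":
            ordered = [(row.gene_a, row.gene_b)]
        elif row.resolved_direction == "b_to_a":
            ordered = [(row.gene_b, row.gene_a)]
        else:  # both
            ordered = [(row.gene_a, row.gene_b), (row.gene_b, row.gene_a)]
        for src, tgt in ordered:
            existing = edges.get((src, tgt))
            if existing is None:
                edges[(src, tgt)] = DirectedEdge(
                    sign=row.sign, provenance=row.provenance
                )
            elif existing.sign != row.sign:
                raise AnnotationConflictError(
                    f"annotation says {src!r}->{tgt!r} is {row.sign}, "
                    f"existing edge is {existing.sign}"
                )
    return DirectedInteractionNetwork(edges=edges, pending=net.pending)


def filter_activating(
    net: DirectedInteractionNetwork,
) -> DirectedInteractionNetwork:
    """Keep only unambiguous activating edges (idempotent)."""
    edges = {
        pair: edge for pair, edge in net.edges.items()
        if edge.sign == "activation"
    }
    return DirectedInteractionNetwork(edges=edges, pending=())


# ---------------------------------------------------------------------------
# Katz centrality and combined scores
# ---------------------------------------------------------------------------

def katz_centrality(
    net: DirectedInteractionNetwork,
    alpha: float = 0.1,
    beta: float = 1.0,
    nodes: Iterable[str] | None = None,
) -> CentralityTable:
    """Exact unnormalized Katz centrality, incoming-edge convention.

    Solves x = beta * 1 + alpha * A^T x, i.e. x_v = beta + alpha *
    sum over incoming neighbors u of x_u, as a dense linear system —
    never by series truncation. The convergence condition
    alpha * spectral_radius(A) < 1 is verified first and violated values
    raise with the measured spectral radius. ``nodes`` may extend the
    node universe with isolated genes (they receive exactly beta), so
    every member of a selected gene set keeps a centrality even when no
    activating edge touches it.
    """
    node_list = sorted(set(net.nodes) | set(nodes or ()))
    n = len(node_list)
    if n == 0:
        return CentralityTable(
            table=pd.DataFrame(columns=["gene", "katz"]),
            alpha=alpha, beta=beta,
        )
    index = {g: i for i, g in enumerate(node_list)}
    A = np.zeros((n, n))
    for (src, tgt) in net.edges:
        A[index[src], index[tgt]] = 1.0
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if net.edges else 0.0
    if alpha * radius >= 1.0:
        raise ValidationError(
            f"alpha={alpha} at or beyond the convergence bound: spectral "
            f"radius {radius:.6g} requires alpha < {1.0 / radius:.6g}"
        )
    x = np.linalg.solve(np.eye(n) - alpha * A.T, np.full(n, float(beta)))
    table = pd.DataFrame({"gene": node_list, "katz": x})
    table = table.sort_values(
        ["katz", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    logger.info(
        "Katz centrality over %d nodes, %d edges (spectral radius %.4g)",
        n, net.n_edges, radius,
    )
    return CentralityTable(table=table, alpha=alpha, beta=beta)


def combined_scores(
    katz: CentralityTable, freq: GeneScoreTable | Mapping[str, int]
) -> CentralityTable:
    """Multiply each gene's centrality by its targeting-frequency score.

    Every gene in the centrality table must carry a frequency score;
    a missing gene is a hard error. The result is sorted by combined
    score descending (gene symbol ascending on ties).
    """
    scores = freq.scores if isinstance(freq, GeneScoreTable) else dict(freq)
    missing = [g for g in katz.table["gene"] if g not in scores]
    if missing:
        raise ValidationError(
            f"{len(missing)} network gene(s) missing from the score table, "
            f"e.g. {missing[:3]}"
        )
    table = katz.table[["gene", "katz"]].copy()
    table["frequency_score"] = [scores[g] for g in table["gene"]]
    table["combined"] = table["katz"] * table["frequency_score"]
    table = table.sort_values(
        ["combined", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return CentralityTable(table=table, alpha=katz.alpha, beta=katz.beta)
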