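"""Permutation null for target-set convergence and interconnectivity.

The question: does the observed signature concentrate its targeting on a
coherent gene set more than a random signature of the same composition
would? Two statistics answer it. The *sum statistic* is the summed
frequency score of the top-k genes (convergence on a specific set); the
*edge statistic* is, per confidence threshold, the number of PPI edges
among those same top-k genes (their functional interconnectedness). The
null resamples signatures of matched size — the same number of high and
low miRNAs drawn uniformly without replacement from all miRNAs in the
interaction table — and scores each one exactly as the observed signature
was scored.

Two empirical p-value conventions are reported for every statistic:

* ``p_strict``  = r / N with r the null values strictly above the observed
  (the "18 of 10000 -> 0.0018" arithmetic);
* ``p_addone`` = (r' + 1) / (N + 1) with r' the null values >= observed —
  never exactly zero, the honest floor when no null value reaches the
  observed one.

The model/results split follows the usual fit idiom:
``ConvergenceTest(signature, mti, ppi).fit(n_iter=10000, seed=1)`` returns
a :class:`PermutationResult` with the distributions, p-values and a
``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MiRNASignature,
    SignatureEntry,
    TargetInteractionTable,
    UndirectedPPINetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "ConvergenceTest",
    "sample_random_signature",
    "edge_count_among",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def sample_random_signature(
    universe: Sequence[str],
    n_high: int,
    n_low: int,
    rng: np.random.Generator,
) -> MiRNASignature:
    """Draw a composition-matched random signature.

    ``n_high + n_low`` distinct miRNAs are drawn uniformly without
    replacement from ``universe``; the first ``n_high`` are labeled high,
    the remainder low, so the two groups never overlap.
    """
    total = n_high + n_low
    if len(universe) < total:
        raise ValidationError(
            f"universe of {len(universe)} miRNAs cannot supply "
            f"{total} distinct draws"
        )
    idx = rng.choice(len(universe), size=total, replace=False)
    entries = []
    for j, i in enumerate(idx):
        direction = "high" if j < n_high else "low"
        entries.append(
            SignatureEntry(universe[i], direction, frozenset({"random"}))
        )
    return MiRNASignature(tuple(entries))


def edge_count_among(
    genes: Iterable[str], ppi: UndirectedPPINetwork, threshold: float
) -> int:
    """PPI edges with both endpoints in ``genes`` and confidence >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    gene_set = set(genes)
    return sum(
        1
        for (a, b), conf in ppi.edges.items()
        if conf >= threshold and a in gene_set and b in gene_set
    )


# ---------------------------------------------------------------------------
# vectorized scoring workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Array-backed view of an MTI table (and optional PPI) for fast resampling.

    miRNAs and genes are indexed in sorted order; targeting is a boolean
    (M, G) matrix, so scoring a signature is two row-slice column sums.
    Gene sorting makes a stable argsort on descending score reproduce the
    lexicographic tie-break used by ``select_top_k``.
    """

    def __init__(
        self,
        mti: TargetInteractionTable,
        ppi: UndirectedPPINetwork | None,
        thresholds: Sequence[float],
    ) -> None:
        self.mirna_ids = list(mti.mirnas)  # sorted distinct display ids
        self.mirna_index = {
            m.casefold(): i for i, m in enumerate(self.mirna_ids)
        }
        self.gene_symbols = np.array(mti.genes)
        gene_index = {g: j for j, g in enumerate(self.gene_symbols)}
        self.targets = np.zeros(
            (len(self.mirna_ids), len(self.gene_symbols)), dtype=bool
        )
        for mirna, gene in mti.pairs:
            self.targets[
                self.mirna_index[mirna.strip().casefold()], gene_index[gene]
            ] = True
        self.adjacency: dict[float, np.ndarray] = {}
        if ppi is not None and thresholds:
            n = len(self.gene_symbols)
            for thr in thresholds:
                adj = np.zeros((n, n), dtype=bool)
                for (a, b), conf in ppi.edges.items():
                    if conf >= thr and a in gene_index and b in gene_index:
                        ia, ib = gene_index[a], gene_index[b]
                        adj[ia, ib] = adj[ib, ia] = True
                self.adjacency[thr] = adj

    def rows_for(self, mirna_ids: Iterable[str]) -> np.ndarray:
        present = [
            self.mirna_index[m.strip().casefold()]
            for m in mirna_ids
            if m.strip().casefold() in self.mirna_index
        ]
        return np.asarray(present, dtype=np.intp)

    def statistics(
        self,
        high_rows: np.ndarray,
        low_rows: np.ndarray,
        k: int,
        thresholds: Sequence[float],
    ) -> tuple[int, dict[float, int]]:
        """(top-k score sum, per-threshold edge count among the top-k genes)."""
        hc = self.targets[high_rows].sum(axis=0)
        lc = self.targets[low_rows].sum(axis=0)
        score = hc.astype(np.int64) - lc.astype(np.int64)
        present = np.flatnonzero((hc + lc) > 0)
        if present.size == 0:
            return 0, {thr: 0 for thr in thresholds}
        order = np.argsort(-score[present], kind="stable")
        top = present[order[: min(k, present.size)]]
        total = int(score[top].sum())
        edges = {
            thr: int(self.adjacency[thr][np.ix_(top, top)].sum()) // 2
            for thr in thresholds
        }
        return total, edges


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

def _p_strict(null: np.ndarray, observed: int) -> float:
    return float((null > observed).sum() / len(null))


def _p_addone(null: np.ndarray, observed: int) -> float:
    return float(((null >= observed).sum() + 1) / (len(null) + 1))


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistics, null distributions and empirical p-values."""

    observed_sum: int
    observed_edges: dict[float, int]
    null_sums: np.ndarray
    null_edges: dict[float, np.ndarray]
    n_iter: int
    k: int
    seed: int | None
    n_high: int
    n_low: int
    universe_size: int
    tie_at_boundary: bool = False

    @property
    def p_strict(self) -> dict[str, object]:
        return {
            "sum": _p_strict(self.null_sums, self.observed_sum),
            "edges": {
                thr: _p_strict(self.null_edges[thr], self.observed_edges[thr])
                for thr in self.observed_edges
            },
        }

    @property
    def p_addone(self) -> dict[str, object]:
        return {
            "sum": _p_addone(self.null_sums, self.observed_sum),
            "edges": {
                thr: _p_addone(self.null_edges[thr], self.observed_edges[thr])
                for thr in self.observed_edges
            },
        }

    def summary(self) -> str:
        """Plain-text summary table of observed statistics and p-values."""
        ps, pa = self.p_strict, self.p_addone
        lines = [
            "Target-set convergence permutation test",
            "=" * 55,
            f"replicates: {self.n_iter}    top-k: {self.k}    "
            f"seed: {self.seed}",
            f"signature: {self.n_high} high + {self.n_low} low miRNAs "
            f"(universe {self.universe_size})",
            "-" * 55,
            f"{'statistic':<22}{'observed':>10}{'p_strict':>11}"
            f"{'p_addone':>11}",
            f"{'top-k score sum':<22}{self.observed_sum:>10}"
            f"{ps['sum']:>11.4g}{pa['sum']:>11.4g}",
        ]
        for thr in sorted(self.observed_edges):
            lines.append(
                f"{f'edges @ {thr:g}':<22}{self.observed_edges[thr]:>10}"
                f"{ps['edges'][thr]:>11.4g}{pa['edges'][thr]:>11.4g}"
            )
        if self.tie_at_boundary:
            lines.append(
                "note: observed top-k cut fell inside a tied score group"
            )
        lines.append("=" * 55)
        return "\n".join(lines)

    def to_files(self, out_dir: Path, stem: str = "permutation") -> list[Path]:
        """Write null distributions (TSV) and a JSON header, deterministically."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        null_df = pd.DataFrame({"null_sum": self.null_sums})
        for thr in sorted(self.null_edges):
            null_df[f"null_edges_{thr:g}"] = self.null_edges[thr]
        null_path = out_dir / f"{stem}_null.tsv"
        null_df.to_csv(null_path, sep="\t", index=False)
        header = {
            "observed_sum": self.observed_sum,
            "observed_edges": {
                f"{thr:g}": v for thr, v in sorted(self.observed_edges.items())
            },
            "n_iter": self.n_iter,
            "k": self.k,
            "seed": self.seed,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "universe_size": self.universe_size,
            "tie_at_boundary": self.tie_at_boundary,
            "p_strict": _jsonable(self.p_strict),
            "p_addone": _jsonable(self.p_addone),
        }
        json_path = out_dir / f"{stem}.json"
        json_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
        return [null_path, json_path]


def _jsonable(p: dict[str, object]) -> dict[str, object]:
    return {
        "sum": p["sum"],
        "edges": {f"{thr:g}": v for thr, v in sorted(p["edges"].items())},  # type: ignore[union-attr]
    }


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ConvergenceTest:
    """Permutation test of signature convergence on a shared gene set.

    Parameters
    ----------
    signature
        The observed signed miRNA signature.
    mti
        Deduplicated miRNA-target interaction table; its distinct miRNAs
        are also the null sampling universe.
    ppi
        Optional undirected PPI network for the edge statistic; omit it
        (with empty ``thresholds``) to test the sum statistic alone.
    top_k
        Number of top-scoring genes entering both statistics (default 100).
    thresholds
        PPI confidence thresholds for the edge statistic
        (default 0.4, 0.7, 0.9).
    """

    def __init__(
        self,
        signature: MiRNASignature,
        mti: TargetInteractionTable,
        ppi: UndirectedPPINetwork | None = None,
        top_k: int = 100,
        thresholds: Sequence[float] = (0.4, 0.7, 0.9),
    ) -> None:
        if top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {top_k}")
        if thresholds and ppi is None:
            raise ValidationError(
                "edge-statistic thresholds given but no PPI network"
            )
        self.signature = signature
        self.mti = mti
        self.ppi = ppi
        self.top_k = top_k
        self.thresholds = tuple(thresholds)
        self._ws = _Workspace(mti, ppi, self.thresholds)

    def fit(self, n_iter: int = 10000, seed: int | None = None) -> PermutationResult:
        """Run the resampling and return a :class:`PermutationResult`."""
        if n_iter < 1:
            raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
        ws = self._ws
        n_high, n_low = self.signature.n_high, self.signature.n_low
        universe = len(ws.mirna_ids)
        if universe < n_high + n_low:
            raise ValidationError(
                f"universe of {universe} miRNAs cannot match a "
                f"{n_high}+{n_low} signature"
            )
        high_rows = ws.rows_for(self.signature.high_ids)
        low_rows = ws.rows_for(self.signature.low_ids)
        n_missing = (n_high + n_low) - (len(high_rows) + len(low_rows))
        if n_missing:
            logger.warning(
                "%d signature miRNA(s) absent from the interaction table",
                n_missing,
            )
        observed_sum, observed_edges = ws.statistics(
            high_rows, low_rows, self.top_k, self.thresholds
        )
        # tie flag for the observed top-k cut
        hc = ws.targets[high_rows].sum(axis=0)
        lc = ws.targets[low_rows].sum(axis=0)
        score = hc.astype(np.int64) - lc.astype(np.int64)
        present = np.flatnonzero((hc + lc) > 0)
        tie = False
        if present.size > self.top_k:
            vals = np.sort(score[present])[::-1]
            tie = bool(vals[self.top_k - 1] == vals[self.top_k])

        rng = np.random.default_rng(seed)
        total = n_high + n_low
        null_sums = np.empty(n_iter, dtype=np.int64)
        null_edges = {
            thr: np.empty(n_iter, dtype=np.int64) for thr in self.thresholds
        }
        for it in range(n_iter):
            draw = rng.choice(universe, size=total, replace=False)
            s, e = ws.statistics(
                draw[:n_high], draw[n_high:], self.top_k, self.thresholds
            )
            null_sums[it] = s
            for thr in self.thresholds:
                null_edges[thr][it] = e[thr]
        return PermutationResult(
            observed_sum=observed_sum,
            observed_edges=observed_edges,
            null_sums=null_sums,
            null_edges=null_edges,
            n_iter=n_iter,
            k=self.top_k,
            seed=seed,
            n_high=n_high,
            n_low=n_low,
            universe_size=universe,
            tie_at_boundary=tie,
        )


def permutation_test(
    signature: MiRNASignature,
    mti: TargetInteractionTable,
    ppi: UndirectedPPINetwork | None = None,
    n_iter: int = 10000,
    k: int = 100,
    thresholds: Sequence[float] = (0.4, 0.7, 0.9),
    seed: int | None = None,
) -> PermutationResult:
    """Functional wrapper over :class:`ConvergenceTest`.

    Equivalent to ``ConvergenceTest(signature, mti, ppi, k,
    thresholds).fit(n_iter, seed)``.
    """
    model = ConvergenceTest(
        signature, mti, ppi, top_k=k, thresholds=thresholds
    )
    return model.fit(n_iter=n_iter, seed=seed)
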