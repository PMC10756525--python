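"""Per-gene targeting-frequency scores and top-gene selection.

For every gene, the number of *distinct* elevated (high) signature miRNAs
with a recorded interaction to it and the number of distinct decreased
(low) ones are counted separately; their difference is the gene's
targeting-frequency score. Genes touched by no signature miRNA are absent
from the table (matching how only targeted genes are ever listed), and
evidence multiplicity never inflates a count because the interaction table
is already deduplicated to unique (miRNA, gene) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .datatypes import (
    MiRNASignature,
    TargetInteractionTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneScoreTable", "TopKSelection", "score_genes",
           "select_top_k", "select_by_threshold"]


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene high/low targeting counts and frequency score.

    ``table`` has columns (gene, high_count, low_count, frequency_score),
    sorted by frequency score descending with ties broken by gene symbol
    ascending — the deterministic order every selection below relies on.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["gene", "high_count", "low_count", "frequency_score"]
        if list(self.table.columns) != expected:
            raise ValidationError(
                f"score table must have columns {expected}"
            )

    @classmethod
    def from_counts(
        cls, counts: dict[str, tuple[int, int]]
    ) -> "GeneScoreTable":
        """Build from gene -> (high_count, low_count); zero-zero genes dropped."""
        rows = [
            (g, h, lo, h - lo)
            for g, (h, lo) in counts.items()
            if h or lo
        ]
        df = pd.DataFrame(
            rows, columns=["gene", "high_count", "low_count", "frequency_score"]
        )
        df = df.sort_values(
            ["frequency_score", "gene"], ascending=[False, True],
            kind="stable",
        ).reset_index(drop=True)
        return cls(df)

    @property
    def scores(self) -> dict[str, int]:
        return dict(zip(self.table["gene"], self.table["frequency_score"]))

    def __len__(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


class TopKSelection(NamedTuple):
    genes: list[str]
    tie_at_boundary: bool


def score_genes(
    signature: MiRNASignature, mti: TargetInteractionTable
) -> GeneScoreTable:
    """Count distinct high/low signature miRNAs targeting each gene.

    Signature miRNAs entirely absent from the interaction table are only
    a logged warning — public interaction databases never cover every
    circulating miRNA — but an empty signature is an error.
    """
    if len(signature) == 0:
        raise ValidationError("cannot score an empty signature")
    high_keys = {m.strip().casefold() for m in signature.high_ids}
    low_keys = {m.strip().casefold() for m in signature.low_ids}
    counts: dict[str, list[int]] = {}
    seen_keys: set[str] = set()
    for mirna, gene in mti.pairs:
        key = mirna.strip().casefold()
        if key in high_keys:
            counts.setdefault(gene, [0, 0])[0] += 1
            seen_keys.add(key)
        elif key in low_keys:
            counts.setdefault(gene, [0, 0])[1] += 1
            seen_keys.add(key)
    missing = (high_keys | low_keys) - seen_keys
    if missing:
        logger.warning(
            "%d of %d signature miRNAs have no interaction record",
            len(missing), len(signature),
        )
    return GeneScoreTable.from_counts(
        {g: (h, lo) for g, (h, lo) in counts.items()}
    )


def select_top_k(scores: GeneScoreTable, k: int) -> TopKSelection:
    """The k highest-scoring genes, deterministically ordered.

    Ties are broken by gene symbol ascending; ``tie_at_boundary`` flags a
    cut through a tied score (the selection could differ under another
    tie-break convention).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    df = scores.table
    genes = df["gene"].tolist()[:k]
    tie = False
    if 0 < len(genes) < len(df):
        boundary = df["frequency_score"].iloc[len(genes) - 1]
        tie = bool(df["frequency_score"].iloc[len(genes)] == boundary)
    return TopKSelection(genes=genes, tie_at_boundary=tie)


def select_by_threshold(scores: GeneScoreTable, min_score: int) -> list[str]:
    """All genes with frequency score >= min_score, in table order."""
    df = scores.table
    return df.loc[df["frequency_score"] >= min_score, "gene"].tolist()
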