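"""Domain types shared across the pipeline.

The analysis moves through a small set of immutable containers: a signed
miRNA *signature* (which circulating miRNAs are elevated or decreased, and
which studies reported them), a deduplicated miRNA->gene *target interaction
table*, an undirected *protein-protein interaction network* with confidence
scores, a signed *directed interaction network* of gene-gene functional
edges, and a manual *annotation table* resolving direction and sign of edges
found only by cross-referencing. Each type validates its own invariants at
construction so downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "DIRECTIONS",
    "SIGNS",
    "MirconvergeError",
    "ValidationError",
    "ConflictingDirectionError",
    "AnnotationConflictError",
    "SignatureEntry",
    "MiRNASignature",
    "TargetInteractionTable",
    "UndirectedPPINetwork",
    "DirectedEdge",
    "PendingInteraction",
    "DirectedInteractionNetwork",
    "AnnotationRow",
    "AnnotationTable",
    "canonical_pair",
]

DIRECTIONS = ("high", "low")
SIGNS = ("activation", "inhibition", "unknown")
RESOLVED_DIRECTIONS = ("a_to_b", "b_to_a", "both", "none")


class MirconvergeError(Exception):
    """Base class for all package errors."""


class ValidationError(MirconvergeError, ValueError):
    """An input violated a structural invariant."""


class ConflictingDirectionError(ValidationError):
    """One miRNA reported both elevated and decreased across studies."""


class AnnotationConflictError(ValidationError):
    """A manual annotation contradicts an existing edge's sign."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair deterministically."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# miRNA signature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureEntry:
    """One differentially expressed miRNA with its reporting studies."""

    mirna_id: str
    direction: str  # "high" (elevated) or "low" (decreased)
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.mirna_id.strip():
            raise ValidationError("empty miRNA identifier")
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if not self.sources:
            raise ValidationError(
                f"miRNA {self.mirna_id!r} has an empty source set"
            )


@dataclass(frozen=True)
class MiRNASignature:
    """Signed, provenance-tagged set of differentially expressed miRNAs.

    Invariants: miRNA identifiers are unique (case-insensitively, after
    trimming) and no miRNA carries both directions — a conflicting report
    across studies is an input error, never silently resolved.
    """

    entries: tuple[SignatureEntry, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            key = e.mirna_id.strip().casefold()
            if key in seen:
                raise ValidationError(
                    f"miRNA {e.mirna_id!r} appears more than once in the signature"
                )
            seen[key] = e.direction

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "MiRNASignature":
        """Aggregate (mirna_id, direction, study) records into a signature.

        Sources accumulate across studies; a miRNA reported "high" by one
        study and "low" by another raises :class:`ConflictingDirectionError`
        naming the miRNA.
        """
        merged: dict[str, tuple[str, str, set[str]]] = {}
        for mirna_id, direction, study in records:
            mid = mirna_id.strip()
            if not mid:
                raise ValidationError("empty miRNA identifier in records")
            if direction not in DIRECTIONS:
                raise ValidationError(
                    f"direction must be one of {DIRECTIONS}, got {direction!r}"
                    f" for miRNA {mid!r}"
                )
            key = mid.casefold()
            if key in merged:
                display, prev_dir, sources = merged[key]
                if prev_dir != direction:
                    raise ConflictingDirectionError(
                        f"miRNA {display!r} reported {prev_dir!r} and "
                        f"{direction!r} by different studies"
                    )
                sources.add(study)
            else:
                merged[key] = (mid, direction, {study})
        entries = tuple(
            SignatureEntry(display, direction, frozenset(sources))
            for display, direction, sources in (
                merged[k] for k in sorted(merged)
            )
        )
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SignatureEntry]:
        return iter(self.entries)

    @property
    def high_ids(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.entries if e.direction == "high")

    @property
    def low_ids(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.entries if e.direction == "low")

    @property
    def n_high(self) -> int:
        return len(self.high_ids)

    @property
    def n_low(self) -> int:
        return len(self.low_ids)

    def subset(self, direction: str) -> "MiRNASignature":
        """Signature restricted to one direction."""
        if direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {direction!r}")
        return MiRNASignature(
            tuple(e for e in self.entries if e.direction == direction)
        )


# ---------------------------------------------------------------------------
# miRNA-target interactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetInteractionTable:
    """Deduplicated miRNA->gene interaction pairs.

    One vote per (miRNA, gene) pair regardless of how many evidence records
    support it; ``record_count_raw`` preserves the pre-deduplication row
    count for logging. miRNA identifiers are matched case-insensitively.
    """

    pairs: frozenset[tuple[str, str]]
    species_filter: str | None = None
    record_count_raw: int = 0

    def __post_init__(self) -> None:
        keys = set()
        for mirna, gene in self.pairs:
            if not mirna.strip() or not gene.strip():
                raise ValidationError(
                    f"empty identifier in pair ({mirna!r}, {gene!r})"
                )
            key = (mirna.strip().casefold(), gene.strip())
            if key in keys:
                raise ValidationError(
                    f"case-duplicate pair for miRNA {mirna!r} and gene {gene!r}"
                )
            keys.add(key)

    @property
    def mirnas(self) -> tuple[str, ...]:
        """Distinct miRNA identifiers, sorted (the sampling universe)."""
        by_key = {m.strip().casefold(): m.strip() for m, _ in self.pairs}
        return tuple(by_key[k] for k in sorted(by_key))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g in self.pairs}))

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# protein-protein interaction network (undirected, scored)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UndirectedPPINetwork:
    """Undirected PPI edges with confidence in [0, 1].

    Unordered pairs are stored once under canonical (lexicographic)
    ordering; self-loops are rejected here (readers drop them upstream
    with a logged count).
    """

    edges: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), conf in self.edges.items():
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) not canonically ordered"
                )
            if not (0.0 <= conf <= 1.0):
                raise ValidationError(
                    f"confidence {conf} outside [0, 1] for edge ({a!r}, {b!r})"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return tuple(sorted(out))

    def confidence(self, a: str, b: str) -> float | None:
        return self.edges.get(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# directed functional-interaction network (signed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectedEdge:
    sign: str  # activation / inhibition / unknown
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValidationError(
                f"sign must be one of {SIGNS}, got {self.sign!r}"
            )


@dataclass(frozen=True)
class PendingInteraction:
    """A not-yet-directed interaction awaiting the trimming stage.

    ``kind`` is ``bidirectional`` (will split into two opposite edges) or
    ``undirected`` (will be dropped).
    """

    gene_a: str
    gene_b: str
    kind: str
    sign: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("bidirectional", "undirected"):
            raise ValidationError(f"unknown pending kind {self.kind!r}")
        if self.sign not in SIGNS:
            raise ValidationError(f"unknown sign {self.sign!r}")
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-interaction on {self.gene_a!r}")


@dataclass(frozen=True)
class DirectedInteractionNetwork:
    """Signed directed gene-gene edges, plus pending un/bidirected rows.

    ``edges`` maps an ordered (source, target) pair to its sign and
    provenance; a given ordered pair appears at most once. ``pending``
    holds rows whose direction marker was ``both`` or ``undirected`` in the
    source file, preserved verbatim for :func:`trim_to_directed`.
    """

    edges: Mapping[tuple[str, str], DirectedEdge] = field(default_factory=dict)
    pending: tuple[PendingInteraction, ...] = ()

    def __post_init__(self) -> None:
        for (src, tgt) in self.edges:
            if src == tgt:
                raise ValidationError(f"self-loop edge on {src!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        out: set[str] = set()
        for src, tgt in self.edges:
            out.add(src)
            out.add(tgt)
        for p in self.pending:
            out.add(p.gene_a)
            out.add(p.gene_b)
        return tuple(sorted(out))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_any_edge(self, a: str, b: str) -> bool:
        """True if an edge exists in either direction between a and b."""
        return (a, b) in self.edges or (b, a) in self.edges

    def signs(self) -> set[str]:
        return {e.sign for e in self.edges.values()}


# ---------------------------------------------------------------------------
# manual annotation of cross-referenced pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRow:
    gene_a: str
    gene_b: str
    resolved_direction: str  # a_to_b / b_to_a / both / none
    sign: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.resolved_direction not in RESOLVED_DIRECTIONS:
            raise ValidationError(
                f"resolved_direction must be one of {RESOLVED_DIRECTIONS}, "
                f"got {self.resolved_direction!r}"
            )
        if self.sign not in SIGNS:
            raise ValidationError(f"unknown sign {self.sign!r}")


@dataclass(frozen=True)
class AnnotationTable:
    """Manual curation outcomes for gene pairs (direction + sign)."""

    rows: tuple[AnnotationRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rows:
            pair = canonical_pair(r.gene_a, r.gene_b)
            if pair in seen:
                raise ValidationError(
                    f"gene pair {pair} annotated more than once"
                )
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.rows)
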