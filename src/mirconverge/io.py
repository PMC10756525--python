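"""Readers and writers for every external table the pipeline touches.

All formats are plain delimited text. Readers validate strictly and return
the domain types from :mod:`mirconverge.datatypes`; writers produce files
that round-trip through the matching reader. Two dialects mirror the public
databases they emulate: the MTI dialect (one evidence record per row, with
species columns on both the miRNA and the gene) and the PPI dialect
(three-column edge list whose combined score is an integer on a 0-1000
scale, normalized to [0, 1] on load).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import (
    AnnotationRow,
    AnnotationTable,
    DirectedEdge,
    DirectedInteractionNetwork,
    MiRNASignature,
    PendingInteraction,
    TargetInteractionTable,
    UndirectedPPINetwork,
    ValidationError,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_signature_lists",
    "read_signature",
    "write_signature",
    "read_mti_table",
    "write_mti_table",
    "read_ppi_network",
    "write_ppi_network",
    "read_directed_network",
    "write_directed_network",
    "read_annotation_table",
    "write_annotation_table",
    "write_results",
]

MTI_REQUIRED_COLUMNS = (
    "miRNA",
    "Species (miRNA)",
    "Target Gene",
    "Species (Target Gene)",
)

_DIRECTION_TOKENS = {"forward", "both", "undirected"}


def _read_delimited(path: Path | str) -> pd.DataFrame:
    """Read a tab- or comma-separated table with a header row."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       comment="#", skip_blank_lines=True)


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def _study_tag(path: Path, text: str) -> str:
    """Study identifier: a '# study: NAME' comment, else the file stem."""
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("study:"):
                return body.split(":", 1)[1].strip()
        elif stripped:
            break
    return path.stem


def read_signature_lists(
    per_study_files: Sequence[Path | str], merge: bool = True
) -> MiRNASignature | list[MiRNASignature]:
    """Pool per-study differential-expression lists into one signature.

    Each file is a two-column (mirna_id, direction) table tagged with a
    study identifier (a ``# study: NAME`` comment or, failing that, the
    file stem). With ``merge=True`` the union over studies is returned and
    sources accumulate per miRNA; a miRNA reported elevated by one study
    and decreased by another is a hard error naming the miRNA. With
    ``merge=False`` a list of per-study signatures is returned.
    """
    if not per_study_files:
        raise ValidationError("no signature files given")
    per_study: list[MiRNASignature] = []
    records: list[tuple[str, str, str]] = []
    for raw in per_study_files:
        path = Path(raw)
        text = path.read_text()
        study = _study_tag(path, text)
        df = _read_delimited(path)
        missing = {"mirna_id", "direction"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        if df.empty:
            raise ValidationError(f"{path}: empty signature file")
        study_records = [
            (row.mirna_id, row.direction, study) for row in df.itertuples()
        ]
        records.extend(study_records)
        per_study.append(MiRNASignature.from_records(study_records))
    if merge:
        return MiRNASignature.from_records(records)
    return per_study


def read_signature(path: Path | str) -> MiRNASignature:
    """Read an aggregated signature (mirna_id, direction, sources) table."""
    df = _read_delimited(path)
    missing = {"mirna_id", "direction", "sources"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    records = []
    for row in df.itertuples():
        for source in str(row.sources).split(";"):
            records.append((row.mirna_id, row.direction, source))
    return MiRNASignature.from_records(records)


def write_signature(signature: MiRNASignature, path: Path | str) -> None:
    lines = ["mirna_id\tdirection\tsources"]
    for e in signature.entries:
        lines.append(
            f"{e.mirna_id}\t{e.direction}\t{';'.join(sorted(e.sources))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# miRNA-target interactions (MTI dialect)
# ---------------------------------------------------------------------------

def read_mti_table(path: Path | str, species: str = "hsa") -> TargetInteractionTable:
    """Load an MTI evidence file and deduplicate to (miRNA, gene) pairs.

    Rows are kept only when both the miRNA and the target gene carry the
    requested species tag; duplicate evidence records for one pair count
    once. Extra columns (evidence type, PMIDs, ...) are ignored.
    """
    df = _read_delimited(path)
    missing = set(MTI_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required MTI columns {sorted(missing)}"
        )
    record_count_raw = len(df)
    mask = (df["Species (miRNA)"].str.strip() == species) & (
        df["Species (Target Gene)"].str.strip() == species
    )
    kept = df.loc[mask]
    if kept.empty:
        raise ValidationError(
            f"{path}: no interaction records left after filtering to "
            f"species {species!r}"
        )
    pairs: dict[tuple[str, str], tuple[str, str]] = {}
    for mirna, gene in zip(kept["miRNA"], kept["Target Gene"]):
        mid, g = mirna.strip(), gene.strip()
        if not mid or not g:
            raise ValidationError(f"{path}: empty miRNA or gene identifier")
        pairs.setdefault((mid.casefold(), g), (mid, g))
    logger.info(
        "MTI %s: %d records -> %d unique pairs (species=%s)",
        path, record_count_raw, len(pairs), species,
    )
    return TargetInteractionTable(
        pairs=frozenset(pairs.values()),
        species_filter=species,
        record_count_raw=record_count_raw,
    )


def write_mti_table(
    table: TargetInteractionTable, path: Path | str
) -> None:
    """Write one record per pair in the MTI dialect (round-trips)."""
    species = table.species_filter or "hsa"
    lines = ["\t".join(MTI_REQUIRED_COLUMNS)]
    for mirna, gene in sorted(table.pairs):
        lines.append(f"{mirna}\t{species}\t{gene}\t{species}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PPI network (STRING-like dialect)
# ---------------------------------------------------------------------------

def read_ppi_network(
    path: Path | str, score_scale: str = "0-1000"
) -> UndirectedPPINetwork:
    """Read a whitespace-separated (protein_a, protein_b, score) edge list.

    ``score_scale`` declares the dialect: ``0-1000`` (integer combined
    scores, divided by 1000 on load) or ``0-1`` (already normalized).
    Scores outside the declared scale are a hard error; self-loops are
    dropped with a logged count; duplicate unordered pairs collapse to the
    canonical ordering (last score wins, which is a no-op for consistent
    inputs).
    """
    if score_scale not in ("0-1000", "0-1"):
        raise ValidationError(f"unknown score scale {score_scale!r}")
    edges: dict[tuple[str, str], float] = {}
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            if lineno == 1 and not _is_number(parts[-1]):
                continue  # header row
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, raw = parts
            score = float(raw)
            if score_scale == "0-1000":
                if not (0 <= score <= 1000):
                    raise ValidationError(
                        f"{path}:{lineno}: score {raw} outside 0-1000"
                    )
                conf = score / 1000.0
            else:
                if not (0.0 <= score <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: score {raw} outside 0-1"
                    )
                conf = score
            if a == b:
                self_loops += 1
                continue
            edges[canonical_pair(a, b)] = conf
    if self_loops:
        logger.info("PPI %s: dropped %d self-loop(s)", path, self_loops)
    return UndirectedPPINetwork(edges=edges)


def write_ppi_network(
    net: UndirectedPPINetwork, path: Path | str, score_scale: str = "0-1000"
) -> None:
    lines = ["protein_a\tprotein_b\tcombined_score"]
    for (a, b), conf in sorted(net.edges.items()):
        if score_scale == "0-1000":
            lines.append(f"{a}\t{b}\t{round(conf * 1000)}")
        else:
            lines.append(f"{a}\t{b}\t{conf:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# directed network + annotations
# ---------------------------------------------------------------------------

def read_directed_network(path: Path | str) -> DirectedInteractionNetwork:
    """Read a (source, target, direction, sign, provenance) table.

    ``direction`` is ``forward`` (a typed edge source->target), ``both``
    or ``undirected``; the latter two are preserved as pending rows for
    the trimming stage. Unknown direction or sign tokens are hard errors
    with the offending line number.
    """
    edges: dict[tuple[str, str], DirectedEdge] = {}
    pending: list[PendingInteraction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["source", "target", "direction", "sign", "provenance"]
        if header != expected:
            raise ValidationError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected 5 columns, got {len(parts)}"
                )
            src, tgt, direction, sign, prov = parts
            if direction not in _DIRECTION_TOKENS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown direction token {direction!r}"
                )
            if sign not in ("activation", "inhibition", "unknown"):
                raise ValidationError(
                    f"{path}:{lineno}: unknown sign token {sign!r}"
                )
            if direction == "forward":
                if (src, tgt) in edges:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate ordered pair "
                        f"({src!r}, {tgt!r})"
                    )
                edges[(src, tgt)] = DirectedEdge(sign=sign, provenance=prov)
            else:
                kind = "bidirectional" if direction == "both" else "undirected"
                pending.append(
                    PendingInteraction(src, tgt, kind, sign, prov)
                )
    return DirectedInteractionNetwork(edges=edges, pending=tuple(pending))


def write_directed_network(
    net: DirectedInteractionNetwork, path: Path | str
) -> None:
    lines = ["source\ttarget\tdirection\tsign\tprovenance"]
    for (src, tgt), edge in sorted(net.edges.items()):
        lines.append(f"{src}\t{tgt}\tforward\t{edge.sign}\t{edge.provenance}")
    for p in sorted(net.pending, key=lambda p: (p.gene_a, p.gene_b, p.kind)):
        token = "both" if p.kind == "bidirectional" else "undirected"
        lines.append(f"{p.gene_a}\t{p.gene_b}\t{token}\t{p.sign}\t{p.provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_table(path: Path | str) -> AnnotationTable:
    """Read manual-curation rows (gene_a, gene_b, direction, sign, provenance)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["gene_a", "gene_b", "resolved_direction", "sign", "provenance"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    rows = tuple(
        AnnotationRow(r.gene_a, r.gene_b, r.resolved_direction, r.sign,
                      r.provenance)
        for r in df.itertuples()
    )
    return AnnotationTable(rows=rows)


def write_annotation_table(ann: AnnotationTable, path: Path | str) -> None:
    lines = ["gene_a\tgene_b\tresolved_direction\tsign\tprovenance"]
    for r in sorted(ann.rows, key=lambda r: (r.gene_a, r.gene_b)):
        lines.append(
            f"{r.gene_a}\t{r.gene_b}\t{r.resolved_direction}\t{r.sign}\t"
            f"{r.provenance}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, object],
    out_dir: Path | str,
    summary: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write result objects as deterministic tab-separated files.

    ``tables`` maps a file stem to a result object: anything exposing a
    ``to_frame()`` method (GeneScoreTable, CentralityTable,
    InfluenceResult), a :class:`PermutationResult` (written as its null
    distributions plus a JSON block), or a plain DataFrame. A
    machine-readable ``run_summary.json`` (parameters, seed, counts) is
    written when ``summary`` is given. Identical inputs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stem, obj in tables.items():
        if hasattr(obj, "to_files"):  # PermutationResult
            written.extend(obj.to_files(out, stem))  # type: ignore[attr-defined]
            continue
        frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
        if not isinstance(frame, pd.DataFrame):
            raise ValidationError(
                f"cannot serialize result {stem!r} of type {type(obj).__name__}"
            )
        path = out / f"{stem}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    if summary is not None:
        path = out / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written
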