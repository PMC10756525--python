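"""Packaged reference datasets.

Two small tables transcribed from the primary ME/CFS circulating-miRNA
literature ship with the package:

* ``mecfs_circulating_signature.tsv`` — the pooled signature of 56
  differentially expressed circulating miRNAs (37 elevated, 19 decreased)
  aggregated from four patient-vs-control studies (Brenu et al. 2014,
  Almenar-Perez et al. 2020, Nepotchatykh et al. 2020, Blauensteiner et
  al. 2021), with the number of independent studies reporting each miRNA
  (four were reported twice; none three times, none in both directions).
* ``mecfs_top_gene_scores.tsv`` — the published targeting-frequency
  scores of the most-targeted genes (score >= 5 for elevated-miRNA
  targets, <= -2 for decreased-miRNA targets).

Only aggregate per-miRNA study counts are public, not which study
reported which miRNA, so the loader synthesizes anonymous source tags
("report-1", "report-2") that preserve the multiplicity without inventing
attributions. Both loaders verify a SHA-256 checksum of the packaged file
before parsing.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .datatypes import MiRNASignature, MirconvergeError
from .scoring import GeneScoreTable

__all__ = ["load_mecfs_signature", "load_mecfs_gene_scores"]

_CHECKSUMS = {
    "mecfs_circulating_signature.tsv":
        "b552294cd203d7c267178b69dce22f2d5ac4ed9547fa8a035f2fa9807034b7ec",
    "mecfs_top_gene_scores.tsv":
        "3bb55cc234f338c6ba903e8a40d4358152a5146ccc5da89c1dbb4c45e02fcf9b",
}


class FixtureChecksumError(MirconvergeError):
    """A packaged dataset does not match its recorded checksum."""


def _read_fixture(name: str) -> bytes:
    data = (resources.files("mirconverge") / "datasets" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureChecksumError(
            f"packaged dataset {name} is corrupted "
            f"(sha256 {digest}, expected {_CHECKSUMS[name]})"
        )
    return data


def load_mecfs_signature() -> MiRNASignature:
    """The pooled 56-miRNA ME/CFS circulating signature (37 high, 19 low)."""
    from io import BytesIO

    df = pd.read_csv(BytesIO(_read_fixture("mecfs_circulating_signature.tsv")),
                     sep="\t")
    records = []
    for row in df.itertuples():
        for i in range(int(row.n_reports)):
            records.append((row.mirna_id, row.direction, f"report-{i + 1}"))
    return MiRNASignature.from_records(records)


def load_mecfs_gene_scores() -> GeneScoreTable:
    """Published targeting-frequency scores of the most-targeted genes.

    Only net scores are public, so counts are reconstructed as
    (max(score, 0), max(-score, 0)) — consistent with the definition
    high_count - low_count = frequency_score and sufficient for
    threshold selection.
    """
    from io import BytesIO

    df = pd.read_csv(BytesIO(_read_fixture("mecfs_top_gene_scores.tsv")),
                     sep="\t")
    counts = {
        row.gene: (max(int(row.frequency_score), 0),
                   max(-int(row.frequency_score), 0))
        for row in df.itertuples()
    }
    return GeneScoreTable.from_counts(counts)
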