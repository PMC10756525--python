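"""End-to-end orchestration with one configuration and deterministic outputs.

A run executes, in order: signature/interaction loading, per-gene
targeting-frequency scoring, the permutation convergence test, directed
network curation (trim, PPI cross-reference, manual annotations,
activating-only filter) over the selected high-score genes, exact Katz
centrality and combined scores, and per-miRNA influence ranking. Every
stage's table is written to the run directory together with one
machine-readable ``run_summary.json`` holding the full configuration,
the seed and the headline numbers; identical inputs and seed produce a
byte-identical output tree.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as mio
from .datatypes import (
    DirectedInteractionNetwork,
    MirconvergeError,
    PendingInteraction,
)
from .influence import build_influence_graph, rank_mirnas
from .network import (
    apply_annotations,
    combined_scores,
    filter_activating,
    find_missing_connections,
    katz_centrality,
    trim_to_directed,
)
from .permutation import ConvergenceTest
from .scoring import score_genes, select_by_threshold, select_top_k

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(MirconvergeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class RunConfig:
    """All inputs and parameters of one pipeline run.

    The parameter defaults are the reference analysis settings: top 100
    genes for the convergence statistics, selection threshold score >= 5,
    10000 permutation replicates, PPI edge thresholds 0.4/0.7/0.9,
    cross-reference threshold 0.95, Katz alpha = 0.1 and beta = 1, and
    influence attenuation 0.1.
    """

    signature_files: tuple[str, ...] = ()
    signature_file: str | None = None  # aggregated dialect alternative
    mti_file: str = ""
    ppi_file: str = ""
    directed_file: str | None = None
    annotation_file: str | None = None
    species: str = "hsa"
    ppi_score_scale: str = "0-1000"
    k: int = 100
    min_score: int = 5
    n_iter: int = 10000
    thresholds: tuple[float, ...] = (0.4, 0.7, 0.9)
    cross_ref_threshold: float = 0.95
    alpha_katz: float = 0.1
    beta_katz: float = 1.0
    alpha_influence: float = 0.1
    max_path_len: int = 8
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signature_files"] = list(self.signature_files)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "signature_files" in d:
            d["signature_files"] = tuple(d["signature_files"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _restrict(
    net: DirectedInteractionNetwork, genes: set[str]
) -> DirectedInteractionNetwork:
    """Subnetwork induced on a gene set (edges and pending rows)."""
    edges = {
        (s, t): e for (s, t), e in net.edges.items()
        if s in genes and t in genes
    }
    pending = tuple(
        p for p in net.pending if p.gene_a in genes and p.gene_b in genes
    )
    return DirectedInteractionNetwork(edges=edges, pending=pending)


def _stage(name: str):
    """Wrap a stage so failures report the stage name and cause."""
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MirconvergeError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return deco


def run_pipeline(cfg: RunConfig, out_dir: Path | str) -> Path:
    """Execute every stage and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ----------------------------------------------------------
    if cfg.signature_file:
        signature = _stage("read_signature")(mio.read_signature)(
            cfg.signature_file
        )
    elif cfg.signature_files:
        signature = _stage("read_signature")(mio.read_signature_lists)(
            [Path(p) for p in cfg.signature_files], merge=True
        )
    else:
        raise PipelineError("stage 'read_signature' failed: no signature input")
    mti = _stage("read_mti")(mio.read_mti_table)(cfg.mti_file, cfg.species)
    ppi = _stage("read_ppi")(mio.read_ppi_network)(
        cfg.ppi_file, cfg.ppi_score_scale
    )

    # --- targeting-frequency scores --------------------------------------
    scores = _stage("score_genes")(score_genes)(signature, mti)
    selected = select_by_threshold(scores, cfg.min_score)
    top = select_top_k(scores, cfg.k)
    logger.info(
        "scored %d genes; %d at score >= %d", len(scores), len(selected),
        cfg.min_score,
    )

    # --- permutation convergence test -------------------------------------
    model = ConvergenceTest(
        signature, mti, ppi, top_k=cfg.k, thresholds=cfg.thresholds
    )
    result = _stage("permutation")(model.fit)(
        n_iter=cfg.n_iter, seed=cfg.seed
    )

    # --- directed network curation ----------------------------------------
    tables: dict[str, object] = {"gene_scores": scores}
    centrality = None
    influence = None
    missing: list[tuple[str, str]] = []
    if cfg.directed_file:
        raw_net = _stage("read_directed")(mio.read_directed_network)(
            cfg.directed_file
        )
        selected_set = set(selected)
        net = _restrict(raw_net, selected_set)
        net = trim_to_directed(net)
        missing = find_missing_connections(net, ppi, cfg.cross_ref_threshold)
        if cfg.annotation_file:
            ann = _stage("read_annotations")(mio.read_annotation_table)(
                cfg.annotation_file
            )
            net = _stage("apply_annotations")(apply_annotations)(net, ann)
        activating = filter_activating(net)
        mio.write_directed_network(activating, out / "network_activating.tsv")

        # --- Katz centrality and combined scores --------------------------
        katz = _stage("katz")(katz_centrality)(
            activating, alpha=cfg.alpha_katz, beta=cfg.beta_katz,
            nodes=selected_set,
        )
        centrality = _stage("combined_scores")(combined_scores)(katz, scores)
        tables["centrality"] = centrality

        # --- influence ranking --------------------------------------------
        graph = build_influence_graph(
            signature.subset("high"), mti, activating
        )
        influence = _stage("influence")(rank_mirnas)(
            signature.subset("high"), graph, centrality,
            alpha=cfg.alpha_influence, max_len=cfg.max_path_len,
        )
        tables["influence"] = influence

    tables["permutation"] = result

    # --- outputs ----------------------------------------------------------
    summary = {
        "config": cfg.to_dict(),
        "signature": {
            "n_mirnas": len(signature),
            "n_high": signature.n_high,
            "n_low": signature.n_low,
        },
        "mti": {
            "n_pairs": len(mti),
            "n_mirnas": len(mti.mirnas),
            "n_genes": len(mti.genes),
            "record_count_raw": mti.record_count_raw,
        },
        "scores": {
            "n_genes": len(scores),
            "n_selected": len(selected),
            "top_k_sum": int(result.observed_sum),
            "top_k_tie_at_boundary": bool(top.tie_at_boundary),
        },
        "permutation": {
            "n_iter": result.n_iter,
            "observed_sum": int(result.observed_sum),
            "observed_edges": {
                f"{t:g}": int(v) for t, v in result.observed_edges.items()
            },
            "p_strict_sum": result.p_strict["sum"],
            "p_addone_sum": result.p_addone["sum"],
            "p_strict_edges": {
                f"{t:g}": v for t, v in result.p_strict["edges"].items()
            },
            "p_addone_edges": {
                f"{t:g}": v for t, v in result.p_addone["edges"].items()
            },
        },
        "missing_connections": len(missing),
        "top_genes": selected[:10],
    }
    if centrality is not None:
        head = centrality.table.head(10)
        summary["top_combined"] = {
            g: round(float(c), 6)
            for g, c in zip(head["gene"], head["combined"])
        }
    if influence is not None:
        head = influence.table.head(10)
        summary["top_mirnas"] = {
            m: round(float(v), 6)
            for m, v in zip(head["mirna_id"], head["influence"])
        }
    if missing:
        (out / "missing_connections.tsv").write_text(
            "gene_a\tgene_b\n"
            + "\n".join(f"{a}\t{b}" for a, b in missing) + "\n"
        )
    mio.write_results(tables, out, summary=summary)
    return out
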