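"""Synthetic regulator-target data with a planted convergent gene cluster.

The generators emulate the combinatorial structure the analysis consumes:
a bipartite miRNA->gene targeting table, an undirected confidence-scored
PPI network, and a signed partially-directed gene-gene network. A
*planted cluster* carries the signal — the designated elevated (high)
signature miRNAs target cluster genes with probability ``p_cluster``
instead of the background ``p_background``, and cluster genes
interconnect at ``q_cluster`` instead of ``q_background`` — so the
permutation test's null behavior (``p_cluster = p_background``,
``q_cluster = q_background``) and power (strong planted effect) can both
be measured. Everything is a pure function of (config, rng seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import (
    DirectedEdge,
    DirectedInteractionNetwork,
    MiRNASignature,
    PendingInteraction,
    SignatureEntry,
    TargetInteractionTable,
    UndirectedPPINetwork,
    ValidationError,
    canonical_pair,
)
from . import io as mio

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_mti_table",
    "generate_ppi",
    "generate_directed_net",
    "generate_signature",
    "generate_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    The default composition (37 high + 19 low miRNAs) matches the pooled
    circulating-miRNA signature the pipeline was designed around, and the
    default effect (60-gene cluster, targeting 0.35 vs background 0.02,
    interconnection 0.5 vs 0.005 over a 300-miRNA x 1000-gene universe)
    is the documented strong planted signal; set ``p_cluster =
    p_background`` and ``q_cluster = q_background`` for a null dataset.
    """

    n_mirna_universe: int = 300
    n_genes: int = 1000
    n_high: int = 37
    n_low: int = 19
    p_background: float = 0.02
    cluster_size: int = 60
    p_cluster: float = 0.35
    q_background: float = 0.005
    q_cluster: float = 0.5
    confidence_background: tuple[float, float] = (0.15, 0.95)
    confidence_cluster: tuple[float, float] = (0.75, 0.99)
    directed_density: float = 0.05
    directed_fraction: float = 0.6
    bidirectional_fraction: float = 0.15
    inhibition_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_background", "p_cluster", "q_background", "q_cluster",
                     "directed_density", "directed_fraction",
                     "bidirectional_fraction", "inhibition_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if self.directed_fraction + self.bidirectional_fraction > 1.0:
            raise ValidationError(
                "directed_fraction + bidirectional_fraction exceeds 1"
            )
        if self.cluster_size > self.n_genes:
            raise ValidationError("cluster_size exceeds n_genes")
        if self.n_high + self.n_low > self.n_mirna_universe:
            raise ValidationError(
                "n_high + n_low exceeds the miRNA universe"
            )
        for name in ("confidence_background", "confidence_cluster"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"{name}={(lo, hi)} not a range in [0, 1]")

    # deterministic designations: the planted high miRNAs are the first
    # n_high of the universe, the low ones the next n_low, and the cluster
    # the first cluster_size genes.
    @property
    def mirna_ids(self) -> list[str]:
        return [f"syn-miR-{i:04d}" for i in range(self.n_mirna_universe)]

    @property
    def gene_symbols(self) -> list[str]:
        return [f"SYNG{i:04d}" for i in range(self.n_genes)]

    @property
    def high_mirnas(self) -> list[str]:
        return self.mirna_ids[: self.n_high]

    @property
    def low_mirnas(self) -> list[str]:
        return self.mirna_ids[self.n_high: self.n_high + self.n_low]

    @property
    def cluster_genes(self) -> list[str]:
        return self.gene_symbols[: self.cluster_size]


@dataclass(frozen=True)
class GroundTruth:
    """Planted-structure labels recorded alongside a generated table."""

    high_mirnas: tuple[str, ...]
    low_mirnas: tuple[str, ...]
    cluster_genes: tuple[str, ...]


def _rng(cfg: SyntheticConfig, rng: np.random.Generator | None,
         stream: int) -> np.random.Generator:
    """Per-artifact generator: cfg.seed spawns one child stream per artifact
    so each generator is reproducible alone and within a bundle."""
    if rng is not None:
        return rng
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream]
    )


def generate_mti_table(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[TargetInteractionTable, GroundTruth]:
    """Bernoulli bipartite targeting with the planted high->cluster block."""
    gen = _rng(cfg, rng, 0)
    p = np.full((cfg.n_mirna_universe, cfg.n_genes), cfg.p_background)
    p[: cfg.n_high, : cfg.cluster_size] = cfg.p_cluster
    hits = gen.random(p.shape) < p
    mirnas, genes = cfg.mirna_ids, cfg.gene_symbols
    pairs = frozenset(
        (mirnas[i], genes[j]) for i, j in zip(*np.nonzero(hits))
    )
    table = TargetInteractionTable(
        pairs=pairs, species_filter="hsa", record_count_raw=len(pairs)
    )
    truth = GroundTruth(
        high_mirnas=tuple(cfg.high_mirnas),
        low_mirnas=tuple(cfg.low_mirnas),
        cluster_genes=tuple(cfg.cluster_genes),
    )
    return table, truth


def generate_ppi(
    cfg: SyntheticConfig,
    cluster_genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> UndirectedPPINetwork:
    """Bernoulli PPI edges, denser and higher-confidence inside the cluster."""
    gen = _rng(cfg, rng, 1)
    genes = cfg.gene_symbols
    cluster = set(cluster_genes if cluster_genes is not None
                  else cfg.cluster_genes)
    in_cluster = np.array([g in cluster for g in genes])
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    both = in_cluster[iu] & in_cluster[ju]
    q = np.where(both, cfg.q_cluster, cfg.q_background)
    present = gen.random(len(iu)) < q
    conf = np.empty(len(iu))
    lo_b, hi_b = cfg.confidence_background
    lo_c, hi_c = cfg.confidence_cluster
    conf_draws = gen.random(len(iu))
    conf = np.where(
        both, lo_c + conf_draws * (hi_c - lo_c),
        lo_b + conf_draws * (hi_b - lo_b),
    )
    edges = {
        canonical_pair(genes[i], genes[j]): float(c)
        for i, j, c in zip(iu[present], ju[present], conf[present])
    }
    return UndirectedPPINetwork(edges=edges)


def generate_directed_net(
    cfg: SyntheticConfig,
    genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> DirectedInteractionNetwork:
    """Random signed, partially directed network (pre-trimming).

    Each unordered gene pair hosts an interaction with probability
    ``directed_density``; it is directed / bidirectional / undirected with
    the configured fractions, oriented uniformly when directed, and
    inhibiting with probability ``inhibition_fraction`` (activating
    otherwise).
    """
    gen = _rng(cfg, rng, 2)
    pool = genes if genes is not None else cfg.gene_symbols
    edges: dict[tuple[str, str], DirectedEdge] = {}
    pending: list[PendingInteraction] = []
    n = len(pool)
    iu, ju = np.triu_indices(n, k=1)
    present = gen.random(len(iu)) < cfg.directed_density
    cat_draw = gen.random(len(iu))
    sign_draw = gen.random(len(iu))
    orient_draw = gen.random(len(iu))
    for idx in np.flatnonzero(present):
        a, b = pool[iu[idx]], pool[ju[idx]]
        sign = ("inhibition" if sign_draw[idx] < cfg.inhibition_fraction
                else "activation")
        u = cat_draw[idx]
        if u < cfg.directed_fraction:
            src, tgt = (a, b) if orient_draw[idx] < 0.5 else (b, a)
            edges[(src, tgt)] = DirectedEdge(sign=sign, provenance="synthetic")
        elif u < cfg.directed_fraction + cfg.bidirectional_fraction:
            pending.append(
                PendingInteraction(a, b, "bidirectional", sign, "synthetic")
            )
        else:
            pending.append(
                PendingInteraction(a, b, "undirected", sign, "synthetic")
            )
    return DirectedInteractionNetwork(edges=edges, pending=tuple(pending))


def generate_signature(cfg: SyntheticConfig) -> MiRNASignature:
    """The planted signature: designated high miRNAs plus non-planted lows."""
    entries = [
        SignatureEntry(m, "high", frozenset({"synthetic"}))
        for m in cfg.high_mirnas
    ] + [
        SignatureEntry(m, "low", frozenset({"synthetic"}))
        for m in cfg.low_mirnas
    ]
    return MiRNASignature(tuple(entries))


def generate_bundle(
    cfg: SyntheticConfig, out_dir: Path | str
) -> dict[str, Path]:
    """Generate and write every artifact in its io dialect.

    Writes mti.tsv, ppi.tsv, directed.tsv, signature.tsv and
    ground_truth.tsv under ``out_dir``; returns the path of each.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mti, truth = generate_mti_table(cfg)
    ppi = generate_ppi(cfg)
    directed = generate_directed_net(cfg)
    signature = generate_signature(cfg)
    paths = {
        "mti": out / "mti.tsv",
        "ppi": out / "ppi.tsv",
        "directed": out / "directed.tsv",
        "signature": out / "signature.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    mio.write_mti_table(mti, paths["mti"])
    mio.write_ppi_network(ppi, paths["ppi"])
    mio.write_directed_network(directed, paths["directed"])
    mio.write_signature(signature, paths["signature"])
    lines = ["name\trole"]
    lines += [f"{m}\tplanted_high" for m in truth.high_mirnas]
    lines += [f"{m}\tplanted_low" for m in truth.low_mirnas]
    lines += [f"{g}\tcluster_gene" for g in truth.cluster_genes]
    paths["ground_truth"].write_text("\n".join(lines) + "\n")
    return paths
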