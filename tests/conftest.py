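"""Shared fixtures: tiny hand-built objects and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirconverge import (
    MiRNASignature,
    SignatureEntry,
    SyntheticConfig,
    TargetInteractionTable,
    UndirectedPPINetwork,
)
from mirconverge.datatypes import canonical_pair

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_signature(high=(), low=(), source="test"):
    entries = tuple(
        SignatureEntry(m, "high", frozenset({source})) for m in high
    ) + tuple(SignatureEntry(m, "low", frozenset({source})) for m in low)
    return MiRNASignature(entries)


def make_mti(pairs):
    return TargetInteractionTable(
        pairs=frozenset(pairs), species_filter="hsa",
        record_count_raw=len(pairs),
    )


def make_ppi(edges):
    """edges: iterable of (a, b, confidence)."""
    return UndirectedPPINetwork(
        edges={canonical_pair(a, b): c for a, b, c in edges}
    )


@pytest.fixture
def small_cfg():
    """Planted-signal config small enough for second-scale tests."""
    return SyntheticConfig(
        n_mirna_universe=80,
        n_genes=200,
        n_high=15,
        n_low=8,
        p_background=0.03,
        cluster_size=25,
        p_cluster=0.4,
        q_background=0.01,
        q_cluster=0.6,
        seed=11,
    )


@pytest.fixture
def null_cfg():
    """No planted signal: cluster probabilities equal background."""
    return SyntheticConfig(
        n_mirna_universe=80,
        n_genes=200,
        n_high=15,
        n_low=8,
        p_background=0.05,
        cluster_size=25,
        p_cluster=0.05,
        q_background=0.02,
        q_cluster=0.02,
        confidence_cluster=(0.15, 0.95),
        seed=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
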