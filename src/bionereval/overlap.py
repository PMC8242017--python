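"""Overlap between phenotypic and reference disease networks.

The first evaluation criterion: how many nodes (diseases) and edges a
NER-derived phenotypic network shares with each omics reference network.
Counts are symmetric; reported percentages are relative to the reference
network, with phenotypic-relative percentages emitted alongside.  The shared
edge count is tested against a null in which only the phenotypic network is
randomized (G(n, m) on its node set) while the reference stays fixed — the
statistic evaluates the NER tool, not the omics data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import DiseaseNetwork
from .significance import (
    NullDistribution,
    ZScoreResult,
    decode_pair_index,
    replicate_seed,
    sample_pair_indices,
    zscore,
)

__all__ = [
    "OverlapResult",
    "node_overlap",
    "edge_overlap",
    "overlap_significance",
    "simultaneous_overlap",
    "overlaps_to_frame",
]


@dataclass
class OverlapResult:
    """Node/edge overlap of one phenotypic network with one reference."""

    phenotypic_id: str
    reference_id: str
    shared_nodes: int
    pct_nodes: float  # relative to the reference node count
    shared_edges: int
    pct_edges: float  # relative to the reference edge count
    pct_nodes_phenotypic: float
    pct_edges_phenotypic: float
    z: ZScoreResult | None = None

    @property
    def shapiro_p(self) -> float | None:
        return None if self.z is None else self.z.shapiro_p


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def node_overlap(a: DiseaseNetwork, ref: DiseaseNetwork) -> tuple[int, float]:
    """Shared disease count and its percentage of the reference's nodes."""
    shared = len(a.node_set() & ref.node_set())
    return shared, _pct(shared, ref.n_nodes)


def edge_overlap(a: DiseaseNetwork, ref: DiseaseNetwork) -> tuple[int, float]:
    """Shared edge count (weights ignored) and its percentage of the reference's edges."""
    shared = len(a.edge_set() & ref.edge_set())
    return shared, _pct(shared, ref.n_edges)


def _shared_edge_null(
    phen: DiseaseNetwork,
    ref_edges: set[tuple[str, str]],
    n_reps: int,
    seed: int,
) -> NullDistribution:
    """Null shared-edge counts: G(n, m) replicas of ``phen`` vs the fixed reference.

    Works directly on pair indices over the phenotypic node set — the same
    sampler :func:`~bionereval.significance.random_gnm` uses — so no graph
    objects are materialized in the inner loop.
    """
    nodes = sorted(phen.node_set())
    n, m = len(nodes), phen.n_edges
    index = {v: i for i, v in enumerate(nodes)}

    def encode(u: str, v: str) -> int | None:
        iu, iv = index.get(u), index.get(v)
        if iu is None or iv is None:
            return None
        i, j = (iu, iv) if iu < iv else (iv, iu)
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    ref_idx = {k for k in (encode(u, v) for u, v in ref_edges) if k is not None}
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(replicate_seed(seed, rep))
        drawn = sample_pair_indices(n, m, rng)
        samples[rep] = len(ref_idx.intersection(drawn.tolist()))
    return NullDistribution(
        statistic_label=f"shared_edges[{phen.source_id}]",
        samples=samples,
        n_reps=n_reps,
        seed=seed,
    )


def overlap_significance(
    phen: DiseaseNetwork,
    ref: DiseaseNetwork,
    n_reps: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Full overlap record with the shared-edge z-score against the null."""
    if n_reps < 2:
        raise DomainError("overlap_significance requires n_reps >= 2")
    shared_n, pct_n = node_overlap(phen, ref)
    shared_e, pct_e = edge_overlap(phen, ref)
    null = _shared_edge_null(phen, ref.edge_set(), n_reps, seed)
    return OverlapResult(
        phenotypic_id=phen.source_id,
        reference_id=ref.source_id,
        shared_nodes=shared_n,
        pct_nodes=pct_n,
        shared_edges=shared_e,
        pct_edges=pct_e,
        pct_nodes_phenotypic=_pct(shared_n, phen.n_nodes),
        pct_edges_phenotypic=_pct(shared_e, phen.n_edges),
        z=zscore(shared_e, null),
    )


def simultaneous_overlap(
    phen: DiseaseNetwork,
    refs: list[DiseaseNetwork],
    n_reps: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Overlap of ``phen`` with all references at once.

    Shared nodes/edges must be present in the phenotypic network and in every
    reference; percentages are relative to the node/edge intersection of the
    references.  The null randomizes the phenotypic side only, as in the
    pairwise test.
    """
    if len(refs) < 2:
        raise DomainError("simultaneous overlap needs at least 2 references")
    ref_nodes = set.intersection(*(r.node_set() for r in refs))
    ref_edges = set.intersection(*(r.edge_set() for r in refs))
    shared_n = len(phen.node_set() & ref_nodes)
    shared_e = len(phen.edge_set() & ref_edges)
    null = _shared_edge_null(phen, ref_edges, n_reps, seed)
    ref_id = "∩".join(r.source_id for r in refs)
    return OverlapResult(
        phenotypic_id=phen.source_id,
        reference_id=ref_id,
        shared_nodes=shared_n,
        pct_nodes=_pct(shared_n, len(ref_nodes)),
        shared_edges=shared_e,
        pct_edges=_pct(shared_e, len(ref_edges)),
        pct_nodes_phenotypic=_pct(shared_n, phen.n_nodes),
        pct_edges_phenotypic=_pct(shared_e, phen.n_edges),
        z=zscore(shared_e, null),
    )


def overlaps_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Overlap report table, one row per (phenotypic, reference) comparison."""
    rows = []
    for r in results:
        rows.append(
            {
                "phenotypic": r.phenotypic_id,
                "reference": r.reference_id,
                "shared_nodes": r.shared_nodes,
                "pct_nodes": round(r.pct_nodes, 2),
                "shared_edges": r.shared_edges,
                "pct_edges": round(r.pct_edges, 2),
                "pct_nodes_phenotypic": round(r.pct_nodes_phenotypic, 2),
                "pct_edges_phenotypic": round(r.pct_edges_phenotypic, 2),
                "z": None if r.z is None else r.z.z,
                "shapiro_p": r.shapiro_p,
            }
        )
    return pd.DataFrame(rows)
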