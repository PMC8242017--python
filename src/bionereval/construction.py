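"""Disease–disease similarity network construction.

Each disease is represented by the set of entities associated with it (terms
extracted by a NER tool, or genes/proteins/drugs from an omics source).  The
similarity between two diseases is the Jaccard index of their entity sets,
i.e. the complement of the Jaccard distance.  Pairs sharing no entity are
never materialized.

Phenotypic (text-derived) networks are sparsified by keeping only pairs whose
similarity lies strictly above the 95th percentile of the nonzero pairwise
similarities; reference omics networks are kept unfiltered, as their greater
specificity already yields sparse graphs.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from .errors import DomainError
from .model import AssociationTable, DiseaseNetwork

__all__ = [
    "SimilarityRecord",
    "jaccard_similarity",
    "pairwise_similarities",
    "percentile_cutoff",
    "build_network",
]


class SimilarityRecord(NamedTuple):
    """One nonzero disease-pair similarity; ``disease_a < disease_b``."""

    disease_a: str
    disease_b: str
    similarity: float


def jaccard_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| between two non-empty entity sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise DomainError("jaccard_similarity requires non-empty sets")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def pairwise_similarities(
    table: AssociationTable, entity_type: str | None = None
) -> list[SimilarityRecord]:
    """All disease pairs sharing at least one entity, with Jaccard weights.

    Computed via a sparse incidence-matrix product so the cost scales with the
    number of co-occurring pairs, not with all C(n, 2) pairs.
    """
    sets = table.entity_sets(entity_type)
    diseases = sorted(sets)
    if len(diseases) < 2:
        return []
    entity_index: dict[str, int] = {}
    rows, cols = [], []
    for i, d in enumerate(diseases):
        for e in sets[d]:
            j = entity_index.setdefault(e, len(entity_index))
            rows.append(i)
            cols.append(j)
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(diseases), len(entity_index)),
    )
    inter = sparse.triu(m @ m.T, k=1).tocoo()
    sizes = np.asarray(m.sum(axis=1)).ravel()
    out = []
    for i, j, shared in zip(inter.row, inter.col, inter.data):
        union = sizes[i] + sizes[j] - shared
        out.append(
            SimilarityRecord(diseases[i], diseases[j], float(shared) / float(union))
        )
    out.sort()
    return out


def percentile_cutoff(values: Sequence[float], q: float) -> float:
    """q-th percentile of ``values`` under linear interpolation (numpy default)."""
    if len(values) == 0:
        raise DomainError("percentile of an empty list is undefined")
    if not (0.0 <= q <= 100.0):
        raise DomainError(f"percentile q={q} outside [0, 100]")
    return float(np.percentile(np.asarray(values, dtype=float), q))


def build_network(
    table: AssociationTable,
    threshold_percentile: float | None = None,
    entity_type: str | None = None,
) -> DiseaseNetwork:
    """Build the disease–disease network for one association table.

    With ``threshold_percentile`` set (95 for phenotypic networks), only pairs
    strictly above the percentile cutoff — computed over the nonzero pairwise
    similarities of this table — become edges; ties at the cutoff are dropped.
    With ``None``, every nonzero-similarity pair becomes an edge.  Diseases
    left without any retained edge do not appear in the node set.
    """
    records = pairwise_similarities(table, entity_type)
    if threshold_percentile is not None and records:
        cutoff = percentile_cutoff([r.similarity for r in records], threshold_percentile)
        records = [r for r in records if r.similarity > cutoff]
    g = nx.Graph()
    for a, b, s in records:
        g.add_edge(a, b, weight=s)
    return DiseaseNetwork(
        g, source_id=table.source_id, threshold_percentile=threshold_percentile
    )
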