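"""Louvain communities and their coincidence with disease categories.

The structural hypothesis under test: a faithful NER tool produces a disease
network whose Louvain communities line up with the top-level categories of
disease-classification systems (MeSH, DO, ICD-10-CM).  For each community we
find its majority category among the members present in the category map and
the proportion of mapped members in that category; the aggregate coincidence
ratio is the mapped-size-weighted mean of those proportions.  Significance is
assessed against the same statistic on G(n, m) randomizations.

Community detection uses the Louvain multilevel algorithm (igraph's C
implementation), seeded through Python's ``random`` state so the "best
partition" is reproducible; modularity Q is recomputed independently with
networkx on the returned assignment.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import NamedTuple

import igraph
import networkx as nx
import pandas as pd

from .errors import DomainError
from .model import CategoryMap, DiseaseNetwork
from .significance import ZScoreResult, build_null, replicate_seed, zscore

__all__ = [
    "Partition",
    "CommunityCoincidence",
    "CoincidenceResult",
    "louvain_best_partition",
    "community_coincidence",
    "coincidence_significance",
    "category_profile",
]


@dataclass
class Partition:
    """A community assignment with its (weighted) modularity Q."""

    assignment: dict[str, int]
    modularity_q: float
    seed: int
    resolution: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[cid] for cid in sorted(groups)]


class CommunityCoincidence(NamedTuple):
    """Per-community majority-category summary."""

    community_id: int
    size: int
    n_mapped: int
    majority_category: str
    proportion: float
    tied: bool


@dataclass
class CoincidenceResult:
    """Coincidence of a partition's communities with one classification system."""

    system_id: str
    network_id: str
    n_communities: int
    per_community: list[CommunityCoincidence]
    ratio: float
    n_unmapped_communities: int = 0
    z: ZScoreResult | None = None

    @property
    def shapiro_p(self) -> float | None:
        return None if self.z is None else self.z.shapiro_p


def louvain_best_partition(
    net: DiseaseNetwork, seed: int, resolution: float = 1.0
) -> Partition:
    """Best Louvain partition of the weighted graph, deterministic given seed."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise DomainError("cannot partition a network without edges")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g[u][v].get("weight", 1.0) for u, v in g.edges]
    ig = igraph.Graph(n=len(nodes), edges=edges)
    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = ig.community_multilevel(weights=weights, resolution=resolution)
    finally:
        _random.setstate(state)
    assignment = {nodes[i]: int(cid) for i, cid in enumerate(clustering.membership)}
    groups: dict[int, set[str]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, set()).add(node)
    q = nx.community.modularity(
        g, list(groups.values()), weight="weight", resolution=resolution
    )
    return Partition(assignment=assignment, modularity_q=float(q), seed=seed,
                     resolution=resolution)


def community_coincidence(
    partition: Partition,
    cmap: CategoryMap,
    network_id: str = "",
    weighted: bool = True,
) -> CoincidenceResult:
    """Majority-category proportion per community and the aggregate ratio.

    Diseases absent from the category map count neither in numerators nor
    denominators; communities with no mapped member are excluded from the
    aggregate and reported in ``n_unmapped_communities``.  Majority ties are
    broken lexicographically on the category id and flagged.  The aggregate
    ratio is the mapped-size-weighted mean of the per-community proportions
    (``weighted=False`` gives the unweighted mean).
    """
    per_community: list[CommunityCoincidence] = []
    n_unmapped = 0
    groups: dict[int, set[str]] = {}
    for node, cid in partition.assignment.items():
        groups.setdefault(cid, set()).add(node)
    for cid in sorted(groups):
        members = groups[cid]
        counts: dict[str, int] = {}
        for d in members:
            cat = cmap.get(d)
            if cat is not None:
                counts[cat] = counts.get(cat, 0) + 1
        n_mapped = sum(counts.values())
        if n_mapped == 0:
            n_unmapped += 1
            continue
        # lexicographically smallest among tied maxima
        top_count = max(counts.values())
        tied_cats = sorted(c for c, k in counts.items() if k == top_count)
        majority = tied_cats[0]
        per_community.append(
            CommunityCoincidence(
                community_id=cid,
                size=len(members),
                n_mapped=n_mapped,
                majority_category=majority,
                proportion=top_count / n_mapped,
                tied=len(tied_cats) > 1,
            )
        )
    if not per_community:
        raise DomainError(
            f"no community contains a disease mapped in system {cmap.system_id!r}"
        )
    if weighted:
        total = sum(c.n_mapped for c in per_community)
        ratio = sum(c.n_mapped * c.proportion for c in per_community) / total
    else:
        ratio = sum(c.proportion for c in per_community) / len(per_community)
    return CoincidenceResult(
        system_id=cmap.system_id,
        network_id=network_id,
        n_communities=len(groups),
        per_community=per_community,
        ratio=float(ratio),
        n_unmapped_communities=n_unmapped,
    )


def coincidence_significance(
    net: DiseaseNetwork,
    cmap: CategoryMap,
    n_reps: int = 1000,
    seed: int = 0,
    resolution: float = 1.0,
    weighted: bool = True,
) -> CoincidenceResult:
    """Coincidence ratio of ``net`` with a z-score against the G(n, m) null.

    Each null replicate re-runs Louvain (with its own derived seed) on a
    random graph with the same node set and edge count, then recomputes the
    coincidence ratio with the same category map.
    """
    observed_partition = louvain_best_partition(net, seed=seed, resolution=resolution)
    observed = community_coincidence(
        observed_partition, cmap, network_id=net.source_id, weighted=weighted
    )

    def ratio_stat(g: DiseaseNetwork) -> float:
        rep_seed = g.build_seed if g.build_seed is not None else seed
        part = louvain_best_partition(g, seed=rep_seed, resolution=resolution)
        return community_coincidence(part, cmap, weighted=weighted).ratio

    null = build_null(
        ratio_stat,
        net,
        n_reps=n_reps,
        seed=seed,
        statistic_label=f"coincidence_ratio[{cmap.system_id}]",
    )
    observed.z = zscore(observed.ratio, null)
    return observed


def category_profile(
    partition: Partition, cmap: CategoryMap, top_k: int = 10
) -> pd.DataFrame:
    """Percent of mapped diseases per top-level category, raw vs community-derived.

    For the ``top_k`` largest categories (by raw disease count among mapped
    diseases) returns two percentages: ``pct_diseases``, the share of mapped
    diseases actually carrying the category, and ``pct_by_community``, the
    share whose Louvain community has that category as its majority.
    """
    mapped = [d for d in partition.assignment if cmap.get(d) is not None]
    if not mapped:
        raise DomainError(f"no diseases mapped in system {cmap.system_id!r}")
    total = len(mapped)
    raw_counts: dict[str, int] = {}
    for d in mapped:
        cat = cmap.get(d)
        raw_counts[cat] = raw_counts.get(cat, 0) + 1
    coincidence = community_coincidence(partition, cmap)
    majority_of_community = {
        c.community_id: c.majority_category for c in coincidence.per_community
    }
    comm_counts: dict[str, int] = {}
    for d in mapped:
        maj = majority_of_community.get(partition.assignment[d])
        if maj is not None:
            comm_counts[maj] = comm_counts.get(maj, 0) + 1
    top = sorted(raw_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    rows = [
        {
            "category_id": cat,
            "n_diseases": count,
            "pct_diseases": round(100.0 * count / total, 2),
            "pct_by_community": round(100.0 * comm_counts.get(cat, 0) / total, 2),
        }
        for cat, count in top
    ]
    return pd.DataFrame(rows)
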