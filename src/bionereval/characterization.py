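"""Topological descriptors of disease networks.

Density, transitivity, degree assortativity and the degree CCDF are computed
on the unweighted skeleton of the graph (the weighted construction only
decides *which* edges exist); modularity is the weighted Q of the best
Louvain partition.  The cross-network "normalized transitivity" score is the
z-score of each network's transitivity against its own G(n, m) null,
min–max-normalized across the set of networks being compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .communities import louvain_best_partition
from .errors import DomainError
from .model import DiseaseNetwork
from .significance import NullDistribution, minmax_normalize, zscore

__all__ = [
    "NetworkSummary",
    "DegreeCCDF",
    "density",
    "transitivity",
    "degree_assortativity",
    "degree_ccdf",
    "summarize",
    "transitivity_null",
    "normalized_transitivity_scores",
    "summaries_to_frame",
]


@dataclass
class NetworkSummary:
    """One row of the per-network characteristics table."""

    source_id: str
    n_nodes: int
    n_edges: int
    density: float
    modularity: float
    transitivity: float
    assortativity: float | None


@dataclass
class DegreeCCDF:
    """Complementary cumulative degree distribution P(K ≥ k) at observed degrees."""

    degrees: np.ndarray
    ccdf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degrees, "ccdf": self.ccdf})


def density(net: DiseaseNetwork) -> float:
    """Fraction of possible edges present: 2m / (n(n−1))."""
    n, m = net.n_nodes, net.n_edges
    if n < 2:
        raise DomainError("density needs at least 2 nodes")
    return 2.0 * m / (n * (n - 1))


def transitivity(net: DiseaseNetwork) -> float:
    """3 × triangles / connected triads; 0 for triad-free graphs."""
    return float(nx.transitivity(net.graph))


def degree_assortativity(net: DiseaseNetwork) -> float | None:
    """Pearson correlation of endpoint degrees over edges; None if degenerate.

    Degenerate means zero degree variance across edge endpoints (e.g. a
    regular graph), where the correlation is undefined.
    """
    g = net.graph
    if g.number_of_edges() < 2:
        raise DomainError("assortativity needs at least 2 edges")
    deg = dict(g.degree)
    x = np.array([deg[u] for u, v in g.edges] + [deg[v] for u, v in g.edges], float)
    y = np.array([deg[v] for u, v in g.edges] + [deg[u] for u, v in g.edges], float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def degree_ccdf(net: DiseaseNetwork) -> DegreeCCDF:
    """P(degree ≥ k) at each observed degree value k, ascending."""
    if net.n_nodes == 0:
        raise DomainError("CCDF of an empty network is undefined")
    degs = np.array(sorted(d for _, d in net.graph.degree))
    values = np.unique(degs)
    ccdf = np.array([(degs >= k).mean() for k in values])
    return DegreeCCDF(degrees=values, ccdf=ccdf)


def summarize(net: DiseaseNetwork, seed: int = 0) -> NetworkSummary:
    """All scalar descriptors for one network (modularity via seeded Louvain)."""
    part = louvain_best_partition(net, seed=seed)
    return NetworkSummary(
        source_id=net.source_id,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=density(net),
        modularity=part.modularity_q,
        transitivity=transitivity(net),
        assortativity=degree_assortativity(net),
    )


def transitivity_null(net: DiseaseNetwork, n_reps: int = 1000, seed: int = 0):
    """G(n, m) null distribution of the transitivity of ``net``."""
    from .significance import build_null

    return build_null(
        transitivity, net, n_reps=n_reps, seed=seed,
        statistic_label=f"transitivity[{net.source_id}]",
    )


def normalized_transitivity_scores(
    observed: Mapping[str, float], nulls: Mapping[str, NullDistribution]
) -> dict[str, float]:
    """Min–max-normalized transitivity z-scores across a set of networks.

    Each network's transitivity is first standardized against its own null;
    the resulting z-scores are then scaled to [0, 1] across the network set,
    so the relatively most/least transitive networks map to 1 and 0.
    """
    labels = sorted(observed)
    if len(labels) < 2:
        raise DomainError("normalized scores need at least 2 networks")
    if sorted(nulls) != labels:
        raise DomainError("observed and null labels differ")
    zs = [zscore(observed[lab], nulls[lab]).z for lab in labels]
    normalized = minmax_normalize(zs)
    return dict(zip(labels, normalized))


def summaries_to_frame(
    summaries: list[NetworkSummary],
    normalized_transitivity: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Characteristics table, one row per network (plus normalized transitivity)."""
    rows = []
    for s in summaries:
        row = {
            "network": s.source_id,
            "nodes": s.n_nodes,
            "edges": s.n_edges,
            "density": round(s.density, 4),
            "modularity": round(s.modularity, 3),
            "transitivity": round(s.transitivity, 4),
            "assortativity": None if s.assortativity is None else round(s.assortativity, 3),
        }
        if normalized_transitivity is not None:
            row["transitivity_normalized_z"] = round(
                normalized_transitivity[s.source_id], 3
            )
        rows.append(row)
    return pd.DataFrame(rows)
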