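"""Core domain types and file formats.

The pipeline revolves around three kinds of objects:

* :class:`AssociationTable` — bipartite disease→entity records, either the
  output of a named-entity-recognition (NER) tool run over disease articles
  (entity type ``term``) or a curated omics source (``gene``, ``protein``,
  ``drug``).
* :class:`DiseaseNetwork` — a weighted, undirected disease–disease similarity
  graph derived from an association table.
* :class:`CategoryMap` — a flat assignment of diseases to the top-level
  categories of one disease-classification system (MeSH, DO, ICD-10-CM, ...).

All identifiers are opaque strings: cross-mapping between vocabularies is an
input file (:class:`IdMapping`), never an online lookup, so runs are fully
reproducible offline.

On-disk formats are plain UTF-8 delimited text (tab preferred, comma
accepted), with named header columns.  Networks are stored as weighted edge
lists with ``#key=value`` metadata header lines; GraphML is accepted as an
alternate dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

ENTITY_TYPES = ("term", "gene", "protein", "drug", "other")

__all__ = [
    "ENTITY_TYPES",
    "AssociationTable",
    "DiseaseNetwork",
    "CategoryMap",
    "IdMapping",
    "read_association_table",
    "write_association_table",
    "read_network",
    "write_network",
    "read_category_maps",
    "write_category_maps",
    "read_id_mapping",
    "apply_id_mapping",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated disease→entity records from one source or tool.

    Parameters
    ----------
    source_id:
        Short label for the producing tool or omics source.
    records:
        ``(disease_id, entity_id, entity_type)`` triples.  At most one record
        per ``(disease_id, entity_id)`` pair.
    """

    source_id: str
    records: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        pairs = set()
        for disease, entity, etype in self.records:
            if not disease or not entity:
                raise ValidationError(
                    f"{self.source_id}: empty disease or entity identifier"
                )
            if etype not in ENTITY_TYPES:
                raise ValidationError(
                    f"{self.source_id}: unknown entity type {etype!r}"
                )
            if (disease, entity) in pairs:
                raise ValidationError(
                    f"{self.source_id}: duplicate record ({disease}, {entity})"
                )
            pairs.add((disease, entity))

    @classmethod
    def from_pairs(
        cls,
        source_id: str,
        pairs: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]],
        entity_type: str = "term",
    ) -> "AssociationTable":
        """Build a table from ``(disease, entity)`` pairs or a disease→entities map."""
        if isinstance(pairs, Mapping):
            triples = {
                (d, e, entity_type) for d, ents in pairs.items() for e in ents
            }
        else:
            triples = {(d, e, entity_type) for d, e in pairs}
        return cls(source_id, frozenset(triples))

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for d, _, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def entity_sets(self, entity_type: str | None = None) -> dict[str, frozenset[str]]:
        """Map each disease to its entity set (optionally one entity type only)."""
        out: dict[str, set[str]] = {}
        for disease, entity, etype in self.records:
            if entity_type is not None and etype != entity_type:
                continue
            out.setdefault(disease, set()).add(entity)
        return {d: frozenset(s) for d, s in out.items()}


class DiseaseNetwork:
    """Weighted undirected disease–disease similarity graph.

    Wraps a :class:`networkx.Graph` whose edge ``weight`` attributes are
    similarities in ``(0, 1]``, plus provenance metadata: the source label,
    the percentile edge filter applied at build time (``None`` for unfiltered
    reference networks) and the seed, if any, used to build it.
    """

    def __init__(
        self,
        graph: nx.Graph,
        source_id: str = "",
        threshold_percentile: float | None = None,
        build_seed: int | None = None,
    ) -> None:
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight", 1.0)
            if not (0.0 < w <= 1.0) or not math.isfinite(w):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) weight {w} outside (0, 1]"
                )
        self.graph = graph
        self.source_id = source_id
        self.threshold_percentile = threshold_percentile
        self.build_seed = build_seed

    # -- convenience views ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        """Canonically ordered (min, max) edge pairs, weights dropped."""
        return {(u, v) if u <= v else (v, u) for u, v in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v].get("weight", 1.0)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        source_id: str = "",
        threshold_percentile: float | None = None,
        build_seed: int | None = None,
    ) -> "DiseaseNetwork":
        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        return cls(g, source_id, threshold_percentile, build_seed)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiseaseNetwork):
            return NotImplemented
        if self.node_set() != other.node_set():
            return False
        if self.edge_set() != other.edge_set():
            return False
        return all(
            math.isclose(self.weight(u, v), other.weight(u, v), rel_tol=1e-12)
            for u, v in self.edge_set()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DiseaseNetwork({self.source_id!r}, n={self.n_nodes}, "
            f"m={self.n_edges}, q={self.threshold_percentile})"
        )


@dataclass(frozen=True)
class CategoryMap:
    """Flat disease→top-level-category assignment for one classification system."""

    system_id: str
    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        for disease, category in self.assignments.items():
            if not disease or not category:
                raise ValidationError(
                    f"{self.system_id}: empty disease or category id"
                )

    def __len__(self) -> int:
        return len(self.assignments)

    def get(self, disease: str) -> str | None:
        return self.assignments.get(disease)


@dataclass(frozen=True)
class IdMapping:
    """Source-vocabulary → canonical disease-id cross-map (a plain input file)."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        if any(not c for c in self.pairs.values()):
            raise ValidationError("empty canonical id in mapping")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Delimited-text helpers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise EmptyInputError(f"{path}: no data rows")


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------


def read_association_table(path: str | Path, source_id: str) -> AssociationTable:
    """Read a disease→entity table (columns ``disease_id, entity_id[, entity_type]``).

    Rows are deduplicated on ``(disease_id, entity_id)``; when duplicates
    disagree on ``entity_type`` the first row wins.  Missing ``entity_type``
    defaults to ``"term"``.
    """
    df = _read_table(path, ("disease_id", "entity_id"))
    if "entity_type" not in df.columns:
        df = df.assign(entity_type="term")
    df = df.drop_duplicates(subset=["disease_id", "entity_id"], keep="first")
    records = frozenset(
        (r.disease_id, r.entity_id, r.entity_type or "term")
        for r in df.itertuples(index=False)
    )
    return AssociationTable(source_id, records)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    rows = sorted(table.records)
    df = pd.DataFrame(rows, columns=["disease_id", "entity_id", "entity_type"])
    df.to_csv(path, sep="\t", index=False)


def apply_id_mapping(
    table: AssociationTable, mapping: IdMapping, drop_unmapped: bool = True
) -> AssociationTable:
    """Canonicalize disease identifiers through a cross-map.

    Diseases mapping to the same canonical id have their entity sets unioned.
    Unmapped diseases are dropped when ``drop_unmapped`` is true, kept verbatim
    otherwise.
    """
    if len(mapping) == 0 and not drop_unmapped:
        return table
    out: set[tuple[str, str, str]] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for disease, entity, etype in sorted(table.records):
        canonical = mapping.pairs.get(disease)
        if canonical is None:
            if drop_unmapped:
                continue
            canonical = disease
        if (canonical, entity) in seen_pairs:
            continue
        seen_pairs.add((canonical, entity))
        out.add((canonical, entity, etype))
    return AssociationTable(table.source_id, frozenset(out))


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_META_KEYS = ("source_id", "threshold_percentile", "build_seed")


def write_network(net: DiseaseNetwork, path: str | Path) -> None:
    """Write a network as a weighted edge list (or GraphML for ``.graphml`` paths).

    Weights are serialized with :func:`repr` so a write/read round trip is
    bit-stable (well beyond 12 significant digits).
    """
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.Graph(net.graph)
        g.graph["source_id"] = net.source_id
        if net.threshold_percentile is not None:
            g.graph["threshold_percentile"] = float(net.threshold_percentile)
        if net.build_seed is not None:
            g.graph["build_seed"] = int(net.build_seed)
        nx.write_graphml(g, path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#source_id={net.source_id}\n")
        if net.threshold_percentile is not None:
            fh.write(f"#threshold_percentile={net.threshold_percentile!r}\n")
        if net.build_seed is not None:
            fh.write(f"#build_seed={net.build_seed}\n")
        fh.write("disease_a\tdisease_b\tweight\n")
        for u, v in sorted(net.edge_set()):
            fh.write(f"{u}\t{v}\t{net.weight(u, v)!r}\n")


def read_network(path: str | Path) -> DiseaseNetwork:
    """Read a network written by :func:`write_network` (edge list or GraphML)."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        meta = g.graph
        tp = meta.get("threshold_percentile")
        seed = meta.get("build_seed")
        clean = nx.Graph()
        for u, v, data in g.edges(data=True):
            clean.add_edge(str(u), str(v), weight=float(data.get("weight", 1.0)))
        clean.add_nodes_from(str(n) for n in g.nodes)
        return DiseaseNetwork(
            clean,
            source_id=str(meta.get("source_id", "")),
            threshold_percentile=None if tp is None else float(tp),
            build_seed=None if seed is None else int(seed),
        )
    meta: dict[str, str] = {}
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if parts[:2] == ["disease_a", "disease_b"]:
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}: malformed edge row {line!r}")
            u, v, w_str = parts
            try:
                w = float(w_str)
            except ValueError as exc:
                raise FormatError(f"{path}: bad weight {w_str!r}") from exc
            if u == v:
                raise ValidationError(f"{path}: self-loop row {line!r}")
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"{path}: weight {w} outside (0, 1]")
            g.add_edge(u, v, weight=w)
    tp = meta.get("threshold_percentile")
    seed = meta.get("build_seed")
    return DiseaseNetwork(
        g,
        source_id=meta.get("source_id", ""),
        threshold_percentile=None if tp in (None, "None") else float(tp),
        build_seed=None if seed in (None, "None") else int(seed),
    )


# ---------------------------------------------------------------------------
# Category maps and id mappings
# ---------------------------------------------------------------------------


def read_category_maps(path: str | Path) -> dict[str, CategoryMap]:
    """Read ``disease_id, system_id, category_id`` rows into one map per system.

    A disease assigned two different top-level categories within one system is
    an input error: callers must resolve multi-category diseases upstream.
    """
    df = _read_table(path, ("disease_id", "system_id", "category_id"))
    maps: dict[str, dict[str, str]] = {}
    conflicts: list[str] = []
    for row in df.itertuples(index=False):
        system = maps.setdefault(row.system_id, {})
        prev = system.get(row.disease_id)
        if prev is not None and prev != row.category_id:
            conflicts.append(f"{row.disease_id} ({row.system_id})")
        system[row.disease_id] = row.category_id
    if conflicts:
        raise ValidationError(
            "conflicting category assignments for: " + ", ".join(sorted(set(conflicts)))
        )
    return {sys_id: CategoryMap(sys_id, asg) for sys_id, asg in maps.items()}


def write_category_maps(maps: Iterable[CategoryMap], path: str | Path) -> None:
    rows = [
        (d, cmap.system_id, c)
        for cmap in maps
        for d, c in sorted(cmap.assignments.items())
    ]
    pd.DataFrame(rows, columns=["disease_id", "system_id", "category_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_id_mapping(path: str | Path) -> IdMapping:
    """Read a two-column ``source_id, canonical_id`` cross-map."""
    df = _read_table(path, ("source_id", "canonical_id"))
    pairs: dict[str, str] = {}
    for row in df.itertuples(index=False):
        prev = pairs.get(row.source_id)
        if prev is not None and prev != row.canonical_id:
            raise ValidationError(f"{path}: source id {row.source_id!r} maps twice")
        pairs[row.source_id] = row.canonical_id
    return IdMapping(pairs)
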