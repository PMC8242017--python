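"""Synthetic disease worlds and simulated NER extraction.

The generator emulates the structure the evaluation framework relies on:
diseases fall into top-level categories, diseases of one category draw most
of their descriptive terms from a category-specific pool (shared symptoms),
and their omics annotations (genes, proteins, drugs) follow the same planted
block structure — so shared terms indicate shared genes.  A simulated NER
tool then degrades the true term table with missed terms (recall < 1) and
spurious global-pool terms (false positives), letting the whole pipeline be
exercised, and its ranking behaviour measured, without any external corpus.

Default scale (600 diseases in 10 categories, 25 terms per disease from
150-term category pools vs a 3000-term global pool, p_within = 0.8) is large
enough for stable Louvain structure yet runs in seconds.  Omics layers are
sparser and more specific (10 entities per disease, p_within = 0.9), and the
reference tables can be subsampled to a fraction of diseases (default 0.4)
to mimic the concentration of curated omics data on well-studied diseases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .communities import coincidence_significance
from .construction import build_network
from .errors import DomainError
from .model import AssociationTable, CategoryMap
from .overlap import overlap_significance
from .scoring import ToolEvaluation, aggregate_evaluations
from .significance import replicate_seed

__all__ = [
    "OmicsParams",
    "GeneratorParams",
    "SyntheticWorld",
    "PipelineConfig",
    "ScenarioResult",
    "generate_world",
    "simulate_tool",
    "reference_tables",
    "benchmark_scenario",
]

CATEGORY_SYSTEM = "SYNCAT"


@dataclass(frozen=True)
class OmicsParams:
    """Per-layer knobs for one omics entity type (genes, proteins or drugs)."""

    entities_per_disease: int = 10
    category_pool_size: int = 80
    global_pool_size: int = 1500
    p_within: float = 0.9

    def validate(self) -> None:
        if not (0.0 <= self.p_within <= 1.0):
            raise DomainError(f"p_within={self.p_within} outside [0, 1]")
        if self.entities_per_disease < 1:
            raise DomainError("entities_per_disease must be >= 1")
        if (
            self.category_pool_size < self.entities_per_disease
            or self.global_pool_size < self.entities_per_disease
        ):
            raise DomainError("pool sizes must be >= entities_per_disease")


@dataclass(frozen=True)
class GeneratorParams:
    """All generator knobs plus the world seed."""

    n_diseases: int = 600
    n_categories: int = 10
    terms_per_disease: int = 25
    category_pool_size: int = 150
    global_pool_size: int = 3000
    p_within: float = 0.8
    genes: OmicsParams = field(default_factory=OmicsParams)
    proteins: OmicsParams = field(default_factory=OmicsParams)
    drugs: OmicsParams = field(default_factory=OmicsParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < self.n_categories or self.n_categories < 1:
            raise DomainError("need n_diseases >= n_categories >= 1")
        if not (0.0 <= self.p_within <= 1.0):
            raise DomainError(f"p_within={self.p_within} outside [0, 1]")
        if (
            self.category_pool_size < self.terms_per_disease
            or self.global_pool_size < self.terms_per_disease
        ):
            raise DomainError("pool sizes must be >= terms_per_disease")
        for layer in (self.genes, self.proteins, self.drugs):
            layer.validate()


@dataclass
class SyntheticWorld:
    """A fully known ground-truth world the pipeline can be run against."""

    diseases: list[str]
    categories: dict[str, str]
    true_terms: dict[str, frozenset[str]]
    true_genes: dict[str, frozenset[str]]
    true_proteins: dict[str, frozenset[str]]
    true_drugs: dict[str, frozenset[str]]
    params: GeneratorParams

    def category_map(self) -> CategoryMap:
        return CategoryMap(CATEGORY_SYSTEM, dict(self.categories))

    def truth_table(self) -> AssociationTable:
        """The error-free term table (an ideal NER tool's output)."""
        return AssociationTable.from_pairs("truth", self.true_terms, "term")


def _draw_layer(
    rng: np.random.Generator,
    diseases: Sequence[str],
    categories: dict[str, str],
    prefix: str,
    n_per_disease: int,
    category_pool_size: int,
    global_pool_size: int,
    p_within: float,
) -> dict[str, frozenset[str]]:
    """Sample one entity layer: category-pool draws with prob p_within, else global."""
    cat_ids = sorted(set(categories.values()))
    cat_pools = {
        c: np.array([f"{prefix}_{c}_{k:04d}" for k in range(category_pool_size)])
        for c in cat_ids
    }
    global_pool = np.array([f"{prefix}_glob_{k:05d}" for k in range(global_pool_size)])
    out: dict[str, frozenset[str]] = {}
    for d in diseases:
        k_within = int(rng.binomial(n_per_disease, p_within))
        pool = cat_pools[categories[d]]
        within = rng.choice(pool, size=min(k_within, pool.size), replace=False)
        k_global = n_per_disease - k_within
        outside = rng.choice(
            global_pool, size=min(k_global, global_pool.size), replace=False
        )
        out[d] = frozenset(within.tolist()) | frozenset(outside.tolist())
    return out


def generate_world(params: GeneratorParams) -> SyntheticWorld:
    """Deterministically generate a world from ``params`` (including its seed).

    Category pools are disjoint across categories and from the global pool by
    construction, so with ``p_within = 1`` diseases of different categories
    share no entities at all.
    """
    rng = np.random.default_rng(params.seed)
    diseases = [f"d{i:04d}" for i in range(params.n_diseases)]
    categories = {
        d: f"cat{(i % params.n_categories):02d}" for i, d in enumerate(diseases)
    }
    true_terms = _draw_layer(
        rng, diseases, categories, "t",
        params.terms_per_disease, params.category_pool_size,
        params.global_pool_size, params.p_within,
    )
    layers = {}
    for name, lp in (("g", params.genes), ("p", params.proteins), ("r", params.drugs)):
        layers[name] = _draw_layer(
            rng, diseases, categories, name,
            lp.entities_per_disease, lp.category_pool_size,
            lp.global_pool_size, lp.p_within,
        )
    return SyntheticWorld(
        diseases=diseases,
        categories=categories,
        true_terms=true_terms,
        true_genes=layers["g"],
        true_proteins=layers["p"],
        true_drugs=layers["r"],
        params=params,
    )


def simulate_tool(
    world: SyntheticWorld,
    recall: float,
    noise_rate: float,
    seed: int,
    source_id: str | None = None,
    confusable: bool = False,
) -> AssociationTable:
    """Simulated NER extraction: keep each true term with probability ``recall``,
    add ``Poisson(noise_rate × terms_per_disease)`` spurious terms per disease.
    Spurious terms come from the global pool; with ``confusable=True`` they
    come from the next category's pool instead, a harsher mode that plants
    false cross-category similarity to stress the coincidence statistic.
    Diseases left with no term are dropped.
    """
    if not (0.0 <= recall <= 1.0):
        raise DomainError(f"recall={recall} outside [0, 1]")
    if noise_rate < 0:
        raise DomainError(f"noise_rate={noise_rate} negative")
    rng = np.random.default_rng(seed)
    p = world.params
    global_pool = np.array([f"t_glob_{k:05d}" for k in range(p.global_pool_size)])
    cat_ids = sorted(set(world.categories.values()))
    next_cat = {c: cat_ids[(i + 1) % len(cat_ids)] for i, c in enumerate(cat_ids)}
    label = source_id or f"tool_r{recall:g}_n{noise_rate:g}"
    extracted: dict[str, frozenset[str]] = {}
    lam = noise_rate * p.terms_per_disease
    for d in world.diseases:
        truth = sorted(world.true_terms[d])
        keep = np.asarray(rng.random(len(truth)) < recall)
        kept = {t for t, k in zip(truth, keep) if k}
        n_spurious = int(rng.poisson(lam))
        if n_spurious:
            if confusable:
                c = next_cat[world.categories[d]]
                pool = np.array(
                    [f"t_{c}_{k:04d}" for k in range(p.category_pool_size)]
                )
            else:
                pool = global_pool
            kept |= set(
                rng.choice(pool, size=min(n_spurious, pool.size), replace=False).tolist()
            )
        if kept:
            extracted[d] = frozenset(kept)
    return AssociationTable.from_pairs(label, extracted, "term")


_LAYER_ATTRS = {
    "genomic": ("true_genes", "gene"),
    "proteomic": ("true_proteins", "protein"),
    "pharmacologic": ("true_drugs", "drug"),
}


def reference_tables(
    world: SyntheticWorld,
    subsample_fraction: float | None = 0.4,
    seed: int = 0,
) -> dict[str, AssociationTable]:
    """True omics association tables, one per layer.

    ``subsample_fraction`` keeps only that share of diseases (per layer, same
    subset), emulating the concentration of curated omics data on a limited
    set of diseases; ``None`` keeps all.
    """
    if subsample_fraction is not None and not (0.0 < subsample_fraction <= 1.0):
        raise DomainError("subsample_fraction must be in (0, 1] or None")
    keep = list(world.diseases)
    if subsample_fraction is not None and subsample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n_keep = max(2, int(round(subsample_fraction * len(keep))))
        keep = sorted(rng.choice(keep, size=n_keep, replace=False).tolist())
    out = {}
    for label, (attr, etype) in _LAYER_ATTRS.items():
        layer: dict[str, frozenset[str]] = getattr(world, attr)
        out[label] = AssociationTable.from_pairs(
            label, {d: layer[d] for d in keep}, etype
        )
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the end-to-end evaluation pipeline."""

    threshold_percentile: float = 95.0
    n_reps: int = 100
    subsample_fraction: float | None = 0.4
    resolution: float = 1.0
    references: tuple[str, ...] = ("genomic", "proteomic", "pharmacologic")


@dataclass
class ScenarioResult:
    """Outcome of one benchmark scenario."""

    evaluations: list[ToolEvaluation]
    true_order: list[str]

    @property
    def ranked_order(self) -> list[str]:
        return [e.tool_id for e in sorted(self.evaluations, key=lambda e: e.rank)]

    @property
    def ranking_correct(self) -> bool:
        """True when the composite ranks tools exactly in fidelity order."""
        return self.ranked_order == self.true_order


def benchmark_scenario(
    params: GeneratorParams,
    tool_specs: Sequence[tuple[float, float]],
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> ScenarioResult:
    """Run the full pipeline on one synthetic world with simulated tools.

    ``tool_specs`` are ``(recall, noise_rate)`` pairs; the ground-truth
    fidelity order sorts by recall descending, then noise ascending.  Returns
    the composite evaluations plus that true order for recovery checks.
    """
    if len(tool_specs) < 2:
        raise DomainError("benchmark needs at least 2 tool specs")
    params = replace(params, seed=replicate_seed(seed, 0))
    world = generate_world(params)
    refs = reference_tables(
        world, subsample_fraction=config.subsample_fraction,
        seed=replicate_seed(seed, 1),
    )
    ref_nets = {
        name: build_network(refs[name], threshold_percentile=None)
        for name in config.references
    }
    cmap = world.category_map()
    overlaps, coincidences = [], []
    for recall, noise in tool_specs:
        label = f"tool_r{recall:g}_n{noise:g}"
        # seeds keyed on the tool spec, not its position, so permuting the
        # spec list leaves every composite unchanged
        key = zlib.crc32(label.encode()) & 0xFFFF
        table = simulate_tool(
            world, recall, noise, seed=replicate_seed(seed, 100_000 + key),
            source_id=label,
        )
        phen = build_network(table, threshold_percentile=config.threshold_percentile)
        for j, (name, ref) in enumerate(sorted(ref_nets.items())):
            overlaps.append(
                overlap_significance(
                    phen, ref, n_reps=config.n_reps,
                    seed=replicate_seed(seed, 200_000 + 8 * key + j),
                )
            )
        coincidences.append(
            coincidence_significance(
                phen, cmap, n_reps=config.n_reps,
                seed=replicate_seed(seed, 300_000 + key),
                resolution=config.resolution,
            )
        )
    evals = aggregate_evaluations(overlaps, coincidences)
    spec_by_label = {
        f"tool_r{r:g}_n{q:g}": (r, q) for r, q in tool_specs
    }
    true_order = sorted(spec_by_label, key=lambda t: (-spec_by_label[t][0], spec_by_label[t][1]))
    return ScenarioResult(evaluations=evals, true_order=true_order)
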