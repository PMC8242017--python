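# Methods

## Model and procedure

The package treats a bio-NER tool as a black box that maps each disease to a
set of extracted entities. Everything downstream operates on that bipartite
disease→entity table:

1. **Similarity.** Disease pairs are scored with the Jaccard index of their
   entity sets. Pairs sharing no entity are never materialized, so the cost
   scales with co-occurring pairs (sparse incidence-matrix product), not with
   all C(n, 2) pairs.
2. **Network.** For text-derived (phenotypic) tables, only pairs strictly
   above the 95th percentile of the nonzero similarities become edges;
   reference omics tables are built identically but unfiltered. Diseases left
   without a retained edge are dropped from the node set.
3. **Characterization.** Density, transitivity, degree assortativity and the
   degree CCDF are computed on the unweighted skeleton — the weighted
   construction decides which edges exist, the descriptors use the standard
   unweighted definitions. Modularity is the weighted Q of the best Louvain
   partition.
4. **Significance.** Every evaluation statistic is recomputed on G(n, m)
   randomizations of the network under test (same node set, same edge count,
   edges uniform over pairs, unit weights). The resulting empirical null
   (default 1000 repetitions) yields a z-score for the observed value and a
   Shapiro–Wilk normality p-value; z-scores built on nulls with p ≤ 0.05
   carry a warning flag rather than being suppressed.
5. **Scoring.** Overlap z-scores (one per reference network) and coincidence
   z-scores (one per classification system) are min–max-normalized across
   tools within each column, averaged per test, and combined with equal
   weights into a composite in [0, 1]; tools are ranked by descending
   composite with ties sharing the minimum rank.

Assumptions: entity identifiers are already normalized (cross-vocabulary
mapping is a plain input file, applied with `apply_id_mapping`; there is no
online terminology lookup); each disease belongs to exactly one top-level
category per classification system (conflicting rows are an input error, by
design — the package does not guess a priority); the texts behind a table are
disease-specific, so co-extracted terms can be read as disease descriptors.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `threshold_percentile` | 95 | phenotypic edge filter; computed per network over its nonzero similarities; "above" is strict, ties at the cutoff are excluded |
| `n_reps` | 1000 | null repetitions; 100 is used in the fast benchmark harness, at the cost of ±~7% relative noise on each z (see limitations) |
| `null_model` | G(n, m) | "same number of randomly connected nodes" read literally; degree-preserving rewiring would shrink overlap z-scores systematically and is deliberately not the default |
| `resolution` | 1.0 | Louvain resolution; left at the modularity definition's natural value |
| coincidence aggregation | mapped-size-weighted mean | keeps tiny communities from dominating the ratio; the unweighted mean is available (`weighted=False`) |
| overlap percentages | reference-relative | shared counts are symmetric; percentages are reported relative to the reference network, with phenotypic-relative values alongside |

Percentiles use numpy's linear-interpolation convention, recorded with the
network metadata. Seeds: one master seed per run; per-replicate seeds derive
from it through `numpy.random.SeedSequence(master, spawn_key=(i,))`, so
replicates are order-insensitive and any run is reproducible from its config.

## Community detection

Louvain communities are computed with igraph's C multilevel implementation,
seeded through Python's `random` state (saved and restored around the call),
which makes the "best partition" deterministic for a given seed. Modularity Q
of the returned assignment is recomputed independently with networkx; on
small graphs the tests additionally verify Q against the explicit
Σ_c (L_c/m − (d_c/2m)²) formula and against exhaustive search over all
partitions. Majority-category ties inside a community are broken toward the
lexicographically smallest category id and flagged in the output.

## Degenerate inputs and numerical choices

- Jaccard of an empty set, percentile of an empty list, partitioning an
  edgeless graph: domain errors, not silent values.
- Assortativity of a degree-regular graph is undefined and reported as
  missing, never as 0.
- A zero-variance null yields a signed-infinity z sentinel (0 if the observed
  value equals the null mean); composite scoring clips infinities to the
  finite extremes of their column before min–max normalization so they land
  exactly on 0 or 1.
- Min–max normalization of an all-equal vector returns 0.5 everywhere with a
  warning.
- Null replicates on which a statistic fails are recorded as missing and
  counted, not fatal.
- Edge weights serialize with full `repr`, making write/read round trips
  bit-stable.

## The synthetic generator

`generate_world` emulates the structural hypothesis the evaluation rests on:
diseases belong to categories; each disease draws its terms from its
category's pool with probability `p_within` (default 0.8), otherwise from a
global pool; gene/protein/drug layers follow the same planted block structure
with their own (sparser, more specific) knobs, so term-sharing and
gene-sharing are correlated by construction. Defaults — 600 diseases, 10
categories, 25 terms per disease, 150-term category pools, 3000-term global
pool — give stable Louvain structure at minutes-scale runtimes. Reference
tables are subsampled to 40% of diseases by default, mimicking the
concentration of curated omics data on well-studied diseases.

`simulate_tool` degrades the true term table with independent term drops
(recall) and Poisson false positives drawn uniformly from the global pool; a
harsher `confusable` mode draws them from a neighboring category's pool
instead, planting false cross-category similarity.

What the generator does **not** emulate: real NER errors are systematic
(ambiguous terms recur across specific disease pairs), term frequencies are
heavy-tailed rather than uniform within pools, categories overlap and are
unbalanced, and omics annotations are biased beyond simple subsampling.
Passing tests therefore demonstrate that the pipeline recovers planted
structure and orders clearly different tools correctly; they do not certify
discrimination between near-equivalent tools on real corpora.

## Known limitations

- **Resolution between similar tools.** With uniform global-pool noise, a
  tool's top-5% network stays almost entirely within-category even at
  moderate degradation: recall loss thins similarity profiles roughly
  uniformly and rare uniform false positives almost never push a wrong pair
  above the percentile cutoff. Two tools of similar (high) fidelity then
  produce networks of near-equal quality, and their composite ordering is
  decided by z-estimation noise — which at 100 null repetitions is of the
  same order as the true gap. The benchmark harness measures exactly this:
  the fidelity-ladder recovery rate it reports rises with `n_reps` and with
  the fidelity gap between tools. This mirrors the method's behaviour on
  real data, where variants of one tool are harder to separate than
  different tools.
- The G(n, m) null conditions only on node and edge counts; hubs make the
  observed statistics easier to beat than under a degree-preserving null.
- The coincidence test assumes single-category diseases at one hierarchy
  level; multi-label or deeper-level structure is out of scope.
- Simultaneous overlap with several references intersects them, which
  shrinks the usable disease set rapidly; it is provided for completeness
  but pairwise overlap is the primary statistic.
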