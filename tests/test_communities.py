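"""Louvain partitions, modularity and category coincidence."""

import itertools

import networkx as nx
import numpy as np
import pytest

from bionereval import (
    CategoryMap,
    DiseaseNetwork,
    DomainError,
    category_profile,
    coincidence_significance,
    community_coincidence,
    louvain_best_partition,
    random_gnm,
)
from bionereval.communities import Partition


def modularity_by_formula(net: DiseaseNetwork, communities: list[set[str]]) -> float:
    """Oracle: Q = sum_c (L_c/m - (d_c/2m)^2), unit weights."""
    m = net.n_edges
    q = 0.0
    for comm in communities:
        lc = sum(1 for u, v in net.edge_set() if u in comm and v in comm)
        dc = sum(d for node, d in net.graph.degree if node in comm)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def best_partition_exhaustive(net: DiseaseNetwork) -> float:
    """Oracle: maximum modularity over all partitions of a tiny node set."""
    nodes = sorted(net.node_set())

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1 :]
            yield part + [{head}]

    return max(modularity_by_formula(net, p) for p in partitions(nodes))


class TestLouvain:
    def test_two_triangles_joined_by_a_bridge(self):
        net = DiseaseNetwork.from_edges(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
             ("c", "x", 1.0)]
        )
        part = louvain_best_partition(net, seed=0)
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset("abc"), frozenset("xyz")}
        # exhaustive oracle over all partitions of 6 nodes
        assert part.modularity_q == pytest.approx(best_partition_exhaustive(net))

    def test_q_at_least_singleton_partition(self):
        for seed in range(5):
            net = random_gnm([f"n{i}" for i in range(20)], 50, seed=seed)
            part = louvain_best_partition(net, seed=seed)
            singletons = [{n} for n in net.node_set()]
            assert part.modularity_q >= modularity_by_formula(net, singletons) - 1e-12

    def test_deterministic_given_seed(self):
        net = random_gnm([f"n{i}" for i in range(80)], 200, seed=1)
        p1 = louvain_best_partition(net, seed=42)
        p2 = louvain_best_partition(net, seed=42)
        assert p1.assignment == p2.assignment

    def test_reported_q_matches_formula(self):
        for seed in range(5):
            net = random_gnm([f"n{i}" for i in range(15)], 30, seed=seed)
            part = louvain_best_partition(net, seed=seed)
            assert part.modularity_q == pytest.approx(
                modularity_by_formula(net, part.communities())
            )

    def test_edgeless_is_domain_error(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(DomainError):
            louvain_best_partition(DiseaseNetwork(g), seed=0)


class TestCoincidence:
    def _partition(self, groups: dict[int, set[str]]) -> Partition:
        assignment = {d: cid for cid, ds in groups.items() for d in ds}
        return Partition(assignment=assignment, modularity_q=0.0, seed=0)

    def test_majority_proportion(self):
        part = self._partition({0: {"d1", "d2", "d3"}})
        cmap = CategoryMap("S", {"d1": "A", "d2": "A", "d3": "B"})
        res = community_coincidence(part, cmap)
        assert res.per_community[0].majority_category == "A"
        assert res.per_community[0].proportion == pytest.approx(2 / 3)
        assert res.ratio == pytest.approx(2 / 3)

    def test_weighted_aggregate(self):
        part = self._partition({0: {f"a{i}" for i in range(4)}, 1: {"b0"}})
        cmap = CategoryMap(
            "S", {"a0": "X", "a1": "X", "a2": "X", "a3": "Y", "b0": "Z"}
        )
        res = community_coincidence(part, cmap)
        # sizes 4 and 1 with proportions 0.75 and 1.0 -> (4*.75 + 1*1)/5
        assert res.ratio == pytest.approx(0.8)
        unweighted = community_coincidence(part, cmap, weighted=False)
        assert unweighted.ratio == pytest.approx((0.75 + 1.0) / 2)

    def test_perfect_planting_gives_ratio_one(self):
        part = self._partition({0: {"a1", "a2"}, 1: {"b1", "b2"}})
        cmap = CategoryMap("S", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert community_coincidence(part, cmap).ratio == 1.0

    def test_unmapped_diseases_and_communities_excluded(self):
        part = self._partition({0: {"d1", "d2", "unmapped"}, 1: {"lost"}})
        cmap = CategoryMap("S", {"d1": "A", "d2": "A"})
        res = community_coincidence(part, cmap)
        assert res.per_community[0].n_mapped == 2
        assert res.per_community[0].proportion == 1.0
        assert res.n_unmapped_communities == 1

    def test_tie_breaks_lexicographically_and_flags(self):
        part = self._partition({0: {"d1", "d2"}})
        cmap = CategoryMap("S", {"d1": "B", "d2": "A"})
        res = community_coincidence(part, cmap)
        assert res.per_community[0].majority_category == "A"
        assert res.per_community[0].tied

    def test_no_mapped_disease_is_domain_error(self):
        part = self._partition({0: {"d1"}})
        with pytest.raises(DomainError):
            community_coincidence(part, CategoryMap("S", {"x": "A"}))

    def test_invariant_under_relabeling(self):
        cmap = CategoryMap("S", {f"d{i}": f"c{i % 3}" for i in range(12)})
        groups = {0: {f"d{i}" for i in range(6)}, 1: {f"d{i}" for i in range(6, 12)}}
        relabeled = {7: groups[1], 3: groups[0]}
        assert (
            community_coincidence(self._partition(groups), cmap).ratio
            == community_coincidence(self._partition(relabeled), cmap).ratio
        )


class TestCoincidenceSignificance:
    def _planted_net(self, seed: int = 0) -> tuple[DiseaseNetwork, CategoryMap]:
        # 4 planted blocks of 12: dense inside, a single chain of bridges
        rng = np.random.default_rng(seed)
        edges = []
        diseases, cats = [], {}
        for b in range(4):
            members = [f"d{b}_{i}" for i in range(12)]
            diseases += members
            for d in members:
                cats[d] = f"cat{b}"
            for u, v in itertools.combinations(members, 2):
                if rng.random() < 0.5:
                    edges.append((u, v, 1.0))
            if b:
                edges.append((f"d{b - 1}_0", f"d{b}_0", 1.0))
        return DiseaseNetwork.from_edges(edges, source_id="planted"), CategoryMap(
            "S", cats
        )

    def test_planted_structure_is_significant(self):
        net, cmap = self._planted_net()
        res = coincidence_significance(net, cmap, n_reps=60, seed=1)
        assert res.ratio > 0.9
        assert res.z.z > 3

    def test_shuffled_labels_are_not_significant(self):
        net, cmap = self._planted_net()
        rng = np.random.default_rng(5)
        diseases = sorted(cmap.assignments)
        shuffled_cats = rng.permutation([cmap.assignments[d] for d in diseases])
        shuffled = CategoryMap("S", dict(zip(diseases, shuffled_cats)))
        zs = [
            coincidence_significance(net, shuffled, n_reps=60, seed=s).z.z
            for s in range(4)
        ]
        # label-permutation oracle: no planted signal left, z should hover near 0
        assert abs(np.mean(zs)) < 3

    def test_null_ratio_bounded_by_majority_baseline(self):
        # if Louvain returned one giant community the ratio is the top category
        # frequency; random-graph partitions cannot do worse on average
        net, cmap = self._planted_net()
        res = coincidence_significance(net, cmap, n_reps=60, seed=2)
        counts = {}
        for c in cmap.assignments.values():
            counts[c] = counts.get(c, 0) + 1
        majority_share = max(counts.values()) / sum(counts.values())
        assert res.z.null.mean >= majority_share - 1e-9


class TestCategoryProfile:
    def test_single_category_map(self):
        part = Partition({f"d{i}": i % 2 for i in range(10)}, 0.0, 0)
        cmap = CategoryMap("S", {f"d{i}": "only" for i in range(10)})
        prof = category_profile(part, cmap, top_k=5)
        assert len(prof) == 1
        assert prof.iloc[0].pct_diseases == 100.0
        assert prof.iloc[0].pct_by_community == 100.0

    def test_percentages_sum_at_most_100(self):
        rng = np.random.default_rng(0)
        part = Partition({f"d{i}": int(rng.integers(4)) for i in range(60)}, 0.0, 0)
        cmap = CategoryMap(
            "S", {f"d{i}": f"c{rng.integers(8)}" for i in range(60)}
        )
        prof = category_profile(part, cmap, top_k=5)
        assert prof.pct_diseases.sum() <= 100.0 + 1e-9
        assert prof.pct_by_community.sum() <= 100.0 + 1e-9
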