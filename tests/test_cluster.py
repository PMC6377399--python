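import numpy as np
import pytest

from ltrdyn.cluster import (ClusterParams, assign_remnants_to_clusters,
                            build_similarity_edges, single_linkage_clusters)
from ltrdyn.simulate import evolve_sequence

from conftest import random_dna


def dfs_components(nodes, edges):
    """Independent connected-components oracle (iterative DFS)."""
    adj = {n: set() for n in nodes}
    for a, b, *_ in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        stack, comp = [n], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return sorted(comps)


def diverge(anc, age_mya, seed):
    return evolve_sequence(anc, age_mya, 1.3e-8, 2.0,
                           np.random.default_rng(seed))


class TestEdges:
    def test_identical_sequences_edge(self, rng):
        s = random_dna(rng, 400)
        edges = build_similarity_edges({"a": s, "b": s})
        assert len(edges) == 1
        a, b, identity, cov_a, cov_b = edges[0]
        assert {a, b} == {"a", "b"}
        assert identity == 100.0 and cov_a == 1.0 and cov_b == 1.0

    def test_mutual_coverage_required(self, rng):
        s = random_dna(rng, 1000)
        # exact half: identity 100 but coverage of the longer one is 0.5
        assert build_similarity_edges({"long": s, "half": s[:500]}) == []

    def test_chain_without_direct_edge(self, rng):
        # A~B and B~C close, A vs C distant: edges {A-B, B-C} only, verified
        # by exhaustive pairwise alignment through the same qualifying rule
        anc1, anc2 = random_dna(rng, 500), random_dna(rng, 500)
        seqs = {"A": diverge(anc1, 2.0, 1), "B": diverge(anc1, 2.0, 2),
                "C": diverge(anc2, 2.0, 3)}
        edges = build_similarity_edges(seqs, ClusterParams(min_identity=80))
        assert sorted((a, b) for a, b, *_ in edges) == [("A", "B")]
        comps = dfs_components(list(seqs), edges)
        assert comps == [["A", "B"], ["C"]]


class TestSingleLinkage:
    def test_transitivity_merges_chain(self):
        cls = single_linkage_clusters(
            ["A", "B", "C"], [("A", "B", 95.0, 1, 1), ("B", "C", 95.0, 1, 1)])
        assert len(cls) == 1
        assert cls[0].members_I == ["A", "B", "C"]
        assert cls[0].cluster_id == "A"

    def test_no_edges_gives_singletons(self):
        cls = single_linkage_clusters(["A", "B"], [])
        assert [(c.cluster_id, c.members_I) for c in cls] == \
            [("A", ["A"]), ("B", ["B"])]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dfs_oracle_on_random_graphs(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 200))
        nodes = [f"n{i:03d}" for i in range(n)]
        edges = []
        for _ in range(int(r.integers(0, 3 * n))):
            a, b = r.choice(n, 2, replace=False)
            edges.append((nodes[a], nodes[b], 90.0, 1.0, 1.0))
        got = sorted(sorted(c.members_I) for c in
                     single_linkage_clusters(nodes, edges))
        assert got == dfs_components(nodes, edges)


@pytest.fixture(scope="module")
def family_ltrs():
    r = np.random.default_rng(99)
    anc1 = random_dna(r, 500)
    anc2 = random_dna(r, 500)
    seqs = {}
    for i in range(4):
        seqs[f"f1_{i}"] = diverge(anc1, 1.0, 10 + i)      # tight family
    for i in range(4):
        seqs[f"f1far_{i}"] = diverge(anc1, 20.0, 20 + i)  # same superfamily
    for i in range(4):
        seqs[f"f2_{i}"] = diverge(anc2, 1.0, 30 + i)      # unrelated family
    return seqs


class TestThresholdStructure:
    def test_family_partition_refines_superfamily(self, family_ltrs):
        nodes = sorted(family_ltrs)
        fam = single_linkage_clusters(
            nodes, build_similarity_edges(family_ltrs, ClusterParams.family()))
        sup = single_linkage_clusters(
            nodes, build_similarity_edges(family_ltrs, ClusterParams.superfamily()))
        sup_of = {m: c.cluster_id for c in sup for m in c.members_I}
        for c in fam:
            assert len({sup_of[m] for m in c.members_I}) == 1
        assert len(fam) >= len(sup)

    def test_unrelated_ancestors_never_co_cluster(self, family_ltrs):
        nodes = sorted(family_ltrs)
        sup = single_linkage_clusters(
            nodes, build_similarity_edges(family_ltrs, ClusterParams.superfamily()))
        by = {m: c.cluster_id for c in sup for m in c.members_I}
        assert by["f1_0"] != by["f2_0"]

    def test_raising_identity_never_decreases_cluster_count(self, family_ltrs):
        nodes = sorted(family_ltrs)
        counts = []
        for ident in (60.0, 80.0, 95.0):
            edges = build_similarity_edges(
                family_ltrs, ClusterParams(min_identity=ident))
            counts.append(len(single_linkage_clusters(nodes, edges)))
        assert counts == sorted(counts)


class TestRemnantAssignment:
    def _setup(self, rng):
        anc1, anc2 = random_dna(rng, 500), random_dna(rng, 500)
        intact = {"I1": diverge(anc1, 1.0, 1), "I2": diverge(anc2, 1.0, 2)}
        edges = build_similarity_edges(intact)
        clusters = single_linkage_clusters(sorted(intact), edges)
        return anc1, anc2, intact, clusters

    def test_remnant_joins_most_similar_cluster(self, rng):
        anc1, _, intact, clusters = self._setup(rng)
        remnants = {"S1": diverge(anc1, 1.5, 7)}
        clusters, unassigned = assign_remnants_to_clusters(
            remnants, {"S1": "SOLO"}, clusters, intact)
        assert unassigned == []
        target = next(c for c in clusters if "I1" in c.members_I)
        assert target.members_S == ["S1"]

    def test_equidistant_tie_goes_to_lower_intact_id(self, rng):
        s = random_dna(rng, 500)
        intact = {"I1": s, "I2": s}
        clusters = single_linkage_clusters(
            ["I1", "I2"], [])  # separate clusters despite identical seqs
        clusters, _ = assign_remnants_to_clusters(
            {"R": s}, {"R": "SOLO"}, clusters, intact)
        assert next(c for c in clusters if c.cluster_id == "I1").members_S == ["R"]
        assert next(c for c in clusters if c.cluster_id == "I2").members_S == []

    def test_diverged_remnant_left_unassigned(self, rng):
        _, _, intact, clusters = self._setup(rng)
        remnants = {"X": random_dna(rng, 500)}
        clusters, unassigned = assign_remnants_to_clusters(
            remnants, {"X": "SOLO"}, clusters, intact)
        assert unassigned == ["X"]
        assert all(not c.members_S for c in clusters)
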