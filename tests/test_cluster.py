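"""Greedy identity clustering and Markov clustering correctness."""

import itertools

import numpy as np
import pytest

from tests.conftest import make_record, oracle_mcl_partition, random_protein
from upomine.cluster import (
    ClusterSet,
    SimilarityGraph,
    greedy_identity_cluster,
    mcl_cluster,
    retain_seed_cluster,
)
from upomine.homology import ScoringScheme, identity_fraction
from upomine.synthetic import mutate_variant


@pytest.fixture(scope="module")
def scheme():
    return ScoringScheme().with_stats()


def mutation_family(rng, n_members, length=120, rate=0.03):
    parent = make_record(random_protein(rng, length), "p0")
    members = [parent]
    for k in range(1, n_members):
        variant = mutate_variant(parent, rate, int(rng.integers(0, 2**31)),
                                 preserve_motifs=False)
        members.append(make_record(variant.residues, f"p{k}"))
    return members


class TestGreedy:
    def test_identical_records_form_one_cluster(self, scheme):
        a = make_record("MKVLHAGWCE" * 10, "a")
        b = make_record("MKVLHAGWCE" * 10, "b")
        cs = greedy_identity_cluster([a, b], scheme=scheme)
        assert cs.clusters == (("a", "b"),)
        assert cs.representatives == ("a",)

    def test_dissimilar_records_form_two_clusters(self, scheme, rng):
        a = make_record(random_protein(rng, 100), "a")
        b = make_record(random_protein(rng, 100), "b")
        cs = greedy_identity_cluster([a, b], scheme=scheme)
        assert len(cs.clusters) == 2

    def test_threshold_domain(self, scheme):
        with pytest.raises(ValueError):
            greedy_identity_cluster([make_record("MKV" * 30)], 1.5)

    def test_partition_and_representative_property_with_allpairs_oracle(
        self, scheme, rng
    ):
        """Word prefilter never changes the partition; every member is
        >= 90% identical to its representative by direct re-alignment."""
        records = []
        k = 0
        for fam in range(5):
            for rec in mutation_family(rng, 4, length=int(rng.integers(80, 160))):
                records.append(make_record(rec.residues, f"r{k}"))
                k += 1
        for _ in range(10):  # singletons
            records.append(make_record(random_protein(rng, 100), f"r{k}"))
            k += 1

        with_filter = greedy_identity_cluster(records, 0.90, 5, scheme)
        without = greedy_identity_cluster(records, 0.90, 0, scheme)
        assert with_filter.clusters == without.clusters
        assert with_filter.ids == frozenset(r.id for r in records)

        by_id = {r.id: r for r in records}
        for cluster, rep in zip(with_filter.clusters, with_filter.representatives):
            for member in cluster:
                assert identity_fraction(by_id[rep], by_id[member], scheme) >= 0.90


class TestClusterSet:
    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClusterSet((("a",), ("a",)), ("a", "a"), "greedy")
        with pytest.raises(ValueError):
            ClusterSet((("a", "b"),), ("c",), "greedy")


def unit_graph(edges, nodes=None):
    nodes = tuple(nodes or sorted({x for e in edges for x in e}))
    return SimilarityGraph(nodes, {frozenset(e): 1.0 for e in edges})


class TestMCL:
    def test_two_disjoint_triangles_stay_separate(self):
        g = unit_graph([("a", "b"), ("b", "c"), ("a", "c"),
                        ("x", "y"), ("y", "z"), ("x", "z")])
        cs = mcl_cluster(g)
        assert set(cs.clusters) == {("a", "b", "c"), ("x", "y", "z")}

    def test_complete_graph_is_one_cluster(self):
        nodes = ["a", "b", "c", "d"]
        g = unit_graph(list(itertools.combinations(nodes, 2)))
        cs = mcl_cluster(g)
        assert cs.clusters == (("a", "b", "c", "d"),)

    def test_isolated_node_is_its_own_cluster(self):
        g = SimilarityGraph(("a", "b", "lonely"), {frozenset(("a", "b")): 2.0})
        cs = mcl_cluster(g)
        assert ("lonely",) in cs.clusters

    def test_matches_fixed_point_oracle_on_small_graphs(self, rng):
        """Seeded small graphs (<= 6 nodes, weights in {1, 2}) against an
        independently coded long-run MCL; clusters never span components."""
        import networkx as nx

        for trial in range(40):
            n = int(rng.integers(2, 7))
            ids = [f"n{i}" for i in range(n)]
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    r = int(rng.integers(0, 3))
                    if r:
                        edges[frozenset((ids[i], ids[j]))] = float(r)
            g = SimilarityGraph(tuple(ids), edges)
            cs = mcl_cluster(g, tol=1e-9, max_iter=2000)
            got = {frozenset(c) for c in cs.clusters}
            want = oracle_mcl_partition(ids, edges, 1.4)
            assert got == want, (trial, edges)

            nxg = nx.Graph()
            nxg.add_nodes_from(ids)
            nxg.add_edges_from(tuple(e) for e in edges)
            comps = list(nx.connected_components(nxg))
            for c in got:
                assert any(c <= comp for comp in comps)

    def test_order_invariance(self, rng):
        ids = [f"n{i}" for i in range(8)]
        edges = {}
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.integers(0, 2):
                    edges[frozenset((ids[i], ids[j]))] = float(rng.integers(1, 5))
        g1 = SimilarityGraph(tuple(ids), edges)
        g2 = SimilarityGraph(tuple(reversed(ids)), dict(reversed(list(edges.items()))))
        assert mcl_cluster(g1).clusters == mcl_cluster(g2).clusters

    def test_negative_weight_rejected(self):
        g = SimilarityGraph(("a", "b"), {frozenset(("a", "b")): -1.0})
        with pytest.raises(ValueError):
            mcl_cluster(g)


class TestSeedRetention:
    def test_singleton_seed(self):
        cs = ClusterSet((("seed",), ("x", "y")), ("seed", "x"), "mcl")
        assert retain_seed_cluster(cs, "seed") == ("seed",)

    def test_five_member_cluster(self):
        members = ("a", "b", "c", "d", "seed")
        cs = ClusterSet((members,), ("a",), "mcl")
        assert retain_seed_cluster(cs, "seed") == members

    def test_absent_seed_errors_naming_it(self):
        cs = ClusterSet((("x",),), ("x",), "mcl")
        with pytest.raises(KeyError, match="ghost"):
            retain_seed_cluster(cs, "ghost")
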