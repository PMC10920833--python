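import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gtclan.align import SequenceRecord
from gtclan.cluster import (
    TwoStageConfig,
    assign_families,
    build_ssn,
    build_supercluster_network,
    components,
    reduce_redundancy,
    run_two_stage,
)
from gtclan.errors import InputError
from gtclan.profiles import ProfileHit
from gtclan.simulate import ProteinFamilySpec, generate_protein_families


def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


@pytest.fixture(scope="module")
def planted():
    return generate_protein_families(ProteinFamilySpec(seed=1))


class TestReduceRedundancy:
    def test_exact_duplicates_collapse(self):
        seqs = [
            SequenceRecord("a", "MKVLATTREWGGSPA"),
            SequenceRecord("b", "MKVLATTREWGGSPA"),
            SequenceRecord("c", "MKVLATTREWGGSPA"),
        ]
        reps, mapping = reduce_redundancy(seqs, 0.99)
        assert len(reps) == 1
        assert set(mapping.values()) == {reps[0].id}

    def test_all_distant_all_representatives(self):
        seqs = [
            SequenceRecord("a", "MKVLATTREW"),
            SequenceRecord("b", "GGSPACHYDN"),
        ]
        reps, _ = reduce_redundancy(seqs, 0.95)
        assert len(reps) == 2

    def test_near_identical_triplet(self):
        base = "MKVLATTREWGGSPACHYDNQRIFEMKVLATTREWG"
        near = base[:20] + "A" + base[21:]  # single substitution, ~97% id
        far = "WWWHHHCCCPPPGGGNNNDDDQQQEEERRRKKKIII"
        seqs = [
            SequenceRecord("a", base),
            SequenceRecord("b", near),
            SequenceRecord("c", far),
        ]
        reps, mapping = reduce_redundancy(seqs, 0.95)
        assert len(reps) == 2
        assert mapping["b"] == mapping["a"]

    def test_bad_threshold_rejected(self):
        with pytest.raises(InputError):
            reduce_redundancy([], 0.3)


class TestBuildSsn:
    def test_threshold_above_max_gives_singletons(self):
        g = build_ssn(["a", "b"], [("a", "b", 50.0)], threshold=100.0)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_strictness(self):
        g = build_ssn(["a", "b"], [("a", "b", 110.0)], threshold=110.0)
        assert g.number_of_edges() == 0

    def test_zero_threshold_connects_positive_scores(self):
        ids = ["a", "b", "c"]
        edges = [("a", "b", 5.0), ("b", "c", 5.0)]
        g = build_ssn(ids, edges, threshold=0.0)
        assert nx.number_connected_components(g) == 1

    def test_asymmetric_pairs_symmetrized_by_max(self):
        g = build_ssn(["a", "b"], [("a", "b", 10.0), ("b", "a", 120.0)], 100.0)
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["weight"] == 120.0

    def test_unknown_node_rejected(self):
        with pytest.raises(InputError):
            build_ssn(["a"], [("a", "zzz", 10.0)], 0.0)

    def test_self_edges_dropped(self):
        g = build_ssn(["a"], [("a", "a", 500.0)], 0.0)
        assert g.number_of_edges() == 0


class TestComponents:
    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        cs = components(g)
        assert len(cs.clusters) == 4
        assert all(len(m) == 1 for m in cs.clusters.values())

    def test_two_cliques_sorted_by_size(self):
        g = nx.Graph()
        g.add_edges_from([("x", "y"), ("a", "b"), ("b", "c"), ("a", "c")])
        cs = components(g)
        assert cs.clusters["C1"] == ["a", "b", "c"]
        assert cs.clusters["C2"] == ["x", "y"]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[int(rng.integers(n))], nodes[int(rng.integers(n))])
                for _ in range(int(rng.integers(0, 40)))
            ]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            expected = union_find_components(nodes, edges)
            got = sorted(
                (frozenset(m) for m in components(g).clusters.values()), key=sorted
            )
            assert got == expected


class TestSuperclusterNetwork:
    def _clusters(self):
        from gtclan.cluster import ClusterSet

        return ClusterSet({"c1": ["s1", "s2"], "c2": ["s3"], "c3": ["s4"]})

    def test_one_direction_above_threshold(self):
        net = build_supercluster_network(
            self._clusters(),
            [ProfileHit("c1", "c2", 170.0), ProfileHit("c2", "c1", 150.0)],
            threshold=160.0,
        )
        assert net.has_edge("c1", "c2")
        assert not net.has_edge("c2", "c1")

    def test_both_directions_two_edges(self):
        net = build_supercluster_network(
            self._clusters(),
            [ProfileHit("c1", "c2", 170.0), ProfileHit("c2", "c1", 171.0)],
            threshold=160.0,
        )
        assert net.has_edge("c1", "c2") and net.has_edge("c2", "c1")

    def test_all_below_threshold_empty(self):
        net = build_supercluster_network(
            self._clusters(), [ProfileHit("c1", "c2", 160.0)], threshold=160.0
        )
        assert net.number_of_edges() == 0

    def test_unknown_cluster_rejected(self):
        with pytest.raises(InputError):
            build_supercluster_network(
                self._clusters(), [ProfileHit("c1", "zzz", 200.0)], 160.0
            )


class TestAssignFamilies:
    def _net(self, sizes, edges):
        net = nx.DiGraph()
        for cid, size in sizes.items():
            net.add_node(cid, members=size)
        net.add_edges_from(edges)
        return net

    def test_size_rule(self):
        net = self._net(
            {"a": 120, "b": 80, "c": 160, "d": 10},
            [("a", "b")],
        )
        fa = assign_families(net, min_family_size=150)
        assert fa.families["F1"] == ["a", "b"]  # 200 members
        assert fa.families["F2"] == ["c"]  # 160 > 150
        assert fa.singletons == ["d"]
        assert fa.family_sizes == {"F1": 200, "F2": 160}

    def test_strict_threshold(self):
        net = self._net({"a": 150}, [])
        fa = assign_families(net, min_family_size=150)
        assert fa.families == {}

    def test_no_edges_all_singletons(self):
        net = self._net({"a": 5, "b": 5}, [])
        fa = assign_families(net, min_family_size=150)
        assert sorted(fa.singletons) == ["a", "b"]

    def test_small_connected_component_unclassified(self):
        net = self._net({"a": 5, "b": 5}, [("a", "b")])
        fa = assign_families(net, min_family_size=150)
        assert fa.unclassified == {"a": ["a", "b"]}
        assert fa.singletons == []

    def test_both_direction_mode(self):
        net = self._net({"a": 100, "b": 100}, [("a", "b")])
        one_way = assign_families(net, 150, require_both_directions=False)
        two_way = assign_families(net, 150, require_both_directions=True)
        assert "F1" in one_way.families
        assert two_way.families == {}


class TestRunTwoStage:
    def test_planted_families_recovered(self, planted):
        result = run_two_stage(planted.records)
        seq2fam = result.sequence_to_family()
        ids = [r.id for r in planted.records]
        ari = adjusted_rand_score(
            [planted.labels[i] for i in ids], [seq2fam[i] for i in ids]
        )
        assert ari == 1.0
        assert result.report["n_families"] == 3

    def test_profile_stage_remerges_fragmented_ssn(self, planted):
        config = TwoStageConfig.internal_defaults()
        config.ssn_threshold = 110.0  # fragments families into many clusters
        result = run_two_stage(planted.records, config)
        assert result.report["n_clusters"] > 3
        seq2fam = result.sequence_to_family()
        ids = [r.id for r in planted.records]
        ari = adjusted_rand_score(
            [planted.labels[i] for i in ids], [seq2fam[i] for i in ids]
        )
        assert ari == 1.0

    def test_single_sequence(self):
        result = run_two_stage([SequenceRecord("only", "MKVLATTREW")])
        assert result.report["n_clusters"] == 1
        assert result.assignment.singletons == ["C1"]

    def test_deterministic_rerun(self, planted):
        r1 = run_two_stage(planted.records)
        r2 = run_two_stage(planted.records)
        assert r1.sequence_to_family() == r2.sequence_to_family()
        assert r1.bit_edges == r2.bit_edges

    def test_order_invariance(self, planted):
        result_fwd = run_two_stage(planted.records)
        result_rev = run_two_stage(list(reversed(planted.records)))
        fwd, rev = result_fwd.sequence_to_family(), result_rev.sequence_to_family()
        groups_fwd = {}
        groups_rev = {}
        for seq, fam in fwd.items():
            groups_fwd.setdefault(fam, set()).add(seq)
        for seq, fam in rev.items():
            groups_rev.setdefault(fam, set()).add(seq)
        assert sorted(groups_fwd.values(), key=sorted) == sorted(
            groups_rev.values(), key=sorted
        )

    def test_ssn_monotonicity_refinement(self, planted):
        from gtclan.align import all_vs_all

        bits, _ = all_vs_all(planted.records)
        ids = [r.id for r in planted.records]
        edges = [
            (ids[i], ids[j], float(bits[i, j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        loose = components(build_ssn(ids, edges, 40.0))
        strict = components(build_ssn(ids, edges, 80.0))
        loose_map = loose.membership()
        strict_map = strict.membership()
        # every strict cluster lies inside one loose cluster (refinement)
        for cid, members in strict.clusters.items():
            assert len({loose_map[s] for s in members}) == 1
        assert len(strict.clusters) >= len(loose.clusters)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            run_two_stage([])
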