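import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtakit.data_io import AffinityRecord, EntityDictionary
from dtakit.errors import DomainError
from dtakit.splits import (
    SimilarityCluster,
    cluster_entities,
    entity_sets,
    greedy_assign_clusters,
    largest_remainder_counts,
    make_entity_cold_split,
    make_similarity_cold_split,
    make_warm_split,
)
from dtakit.synthetic_data import SyntheticSpec, generate_benchmark


def toy_records(n_drugs=10, n_proteins=6, affinity=5.0):
    return [
        AffinityRecord(f"d{i}", f"p{j}", affinity + 0.1 * i + 0.01 * j)
        for i in range(n_drugs)
        for j in range(n_proteins)
    ]


class TestWarmSplit:
    def test_ten_records_split_8_1_1(self):
        records = toy_records(10, 1)
        split = make_warm_split(records, (0.8, 0.1, 0.1), seed=3)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)

    def test_partition_property(self):
        records = toy_records()
        split = make_warm_split(records, seed=11)
        split.validate_partition(len(records))

    def test_same_seed_is_bit_identical(self):
        records = toy_records()
        a = make_warm_split(records, seed=5)
        b = make_warm_split(records, seed=5)
        assert a.train == b.train and a.val == b.val and a.test == b.test

    def test_different_seeds_differ(self):
        records = toy_records()
        assert make_warm_split(records, seed=1).train != make_warm_split(
            records, seed=2
        ).train

    def test_invalid_ratios_rejected(self):
        with pytest.raises(DomainError):
            make_warm_split(toy_records(), (0.5, 0.5, 0.5))

    def test_too_few_records_rejected(self):
        with pytest.raises(DomainError):
            make_warm_split(toy_records(2, 1))


class TestEntityColdSplit:
    def test_no_test_drug_occurs_in_train(self):
        records = toy_records(10, 6)
        split = make_entity_cold_split(records, axis="drug", seed=2)
        sets = entity_sets(records, split, "drug")
        assert not sets["train"] & sets["test"]
        assert not sets["val"] & sets["test"]
        assert not sets["train"] & sets["val"]

    def test_drug_axis_entity_counts(self):
        records = toy_records(10, 6)
        split = make_entity_cold_split(records, axis="drug", seed=2)
        sets = entity_sets(records, split, "drug")
        assert (len(sets["train"]), len(sets["val"]), len(sets["test"])) == (8, 1, 1)

    def test_442_protein_largest_remainder(self):
        # 442 * (0.8, 0.1, 0.1) = (353.6, 44.2, 44.2): one leftover goes to
        # the largest fractional remainder -> (354, 44, 44)
        assert largest_remainder_counts(442, (0.8, 0.1, 0.1)) == (354, 44, 44)

    def test_protein_axis_disjoint(self):
        records = toy_records(4, 12)
        split = make_entity_cold_split(records, axis="protein", seed=0)
        sets = entity_sets(records, split, "protein")
        assert not sets["train"] & sets["test"]

    def test_single_entity_rejected(self):
        records = [AffinityRecord("d0", f"p{j}", 5.0) for j in range(10)]
        with pytest.raises(DomainError):
            make_entity_cold_split(records, axis="drug", seed=0)

    def test_records_follow_their_entity(self):
        records = toy_records(10, 6)
        split = make_entity_cold_split(records, axis="drug", seed=7)
        sets = entity_sets(records, split, "drug")
        for name, idx in split.subsets().items():
            for i in idx:
                assert records[i].drug_id in sets[name]


class TestClustering:
    def test_transitive_closure_merges_chain(self):
        sims = {("A", "B"): 0.6, ("B", "C"): 0.5, ("A", "C"): 0.1}
        fn = lambda a, b: sims[tuple(sorted((a, b)))]
        clusters = cluster_entities({e: e for e in "ABC"}, fn, threshold=0.4)
        assert [set(c.members) for c in clusters] == [{"A", "B", "C"}]

    def test_threshold_is_strict(self):
        sims = {("A", "B"): 0.6, ("B", "C"): 0.55, ("A", "C"): 0.1}
        fn = lambda a, b: sims[tuple(sorted((a, b)))]
        clusters = cluster_entities({e: e for e in "ABC"}, fn, threshold=0.55)
        assert sorted((set(c.members) for c in clusters), key=min) == [
            {"A", "B"}, {"C"},
        ]

    def test_zero_similarity_gives_singletons(self):
        clusters = cluster_entities({e: e for e in "ABCD"}, lambda a, b: 0.0, 0.5)
        assert all(len(c.members) == 1 for c in clusters)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(3, 12),
        threshold=st.floats(0.1, 0.9),
        data=st.data(),
    )
    def test_matches_brute_force_transitive_closure(self, n, threshold, data):
        ids = [f"e{i:02d}" for i in range(n)]
        sims = {
            pair: data.draw(st.floats(0, 1))
            for pair in itertools.combinations(ids, 2)
        }
        fn = lambda a, b: sims[tuple(sorted((a, b)))]
        clusters = cluster_entities({e: e for e in ids}, fn, threshold)
        # brute force: boolean adjacency closure
        adj = {e: {e} for e in ids}
        for (a, b), s in sims.items():
            if s > threshold:
                adj[a].add(b)
                adj[b].add(a)
        changed = True
        while changed:
            changed = False
            for e in ids:
                new = set().union(*(adj[x] for x in adj[e]))
                if new != adj[e]:
                    adj[e] = new
                    changed = True
        expected = {frozenset(v) for v in adj.values()}
        assert {c.members for c in clusters} == expected


class TestGreedyAssignment:
    @staticmethod
    def _clusters(sizes):
        return [
            SimilarityCluster(cluster_id=f"c{i:02d}", members=frozenset({f"c{i:02d}"}),
                              pair_count=s)
            for i, s in enumerate(sizes)
        ]

    def test_ten_singletons_hit_exact_ratio(self):
        assignment, warnings, achieved = greedy_assign_clusters(
            self._clusters([10] * 10), (0.8, 0.1, 0.1)
        )
        counts = {s: sum(1 for v in assignment.values() if v == s)
                  for s in ("train", "val", "test")}
        assert counts == {"train": 8, "val": 1, "test": 1}
        assert achieved == {"train": 0.8, "val": 0.1, "test": 0.1}
        assert not warnings

    def test_50_30_10_10_hand_trace(self):
        # descending order: 50 -> train, 30 -> train (deficit 30 left),
        # 10 -> val, 10 -> test
        clusters = self._clusters([50, 30, 10, 10])
        assignment, _, achieved = greedy_assign_clusters(clusters, (0.8, 0.1, 0.1))
        assert assignment == {"c00": "train", "c01": "train",
                              "c02": "val", "c03": "test"}
        assert achieved == {"train": 0.8, "val": 0.1, "test": 0.1}

    def test_dominant_cluster_warns_and_lands_in_train(self):
        assignment, warnings, _ = greedy_assign_clusters(
            self._clusters([90, 5, 5]), (0.8, 0.1, 0.1)
        )
        assert assignment["c00"] == "train"
        assert warnings  # ratio unattainable


@pytest.fixture(scope="module")
def toy_benchmark():
    records, dicts, _ = generate_benchmark(
        SyntheticSpec(n_drugs=20, n_proteins=20, pair_density=0.6, seed=5)
    )
    return records, dicts


class TestSimilarityColdSplit:

    @pytest.mark.parametrize("threshold", [0.30, 0.40, 0.50])
    def test_drug_axis_no_cross_subset_similarity_above_threshold(
        self, toy_benchmark, threshold
    ):
        from dtakit.audit import morgan_fingerprint, tanimoto

        records, dicts = toy_benchmark
        split = make_similarity_cold_split(
            records, dicts, "drug", threshold, seed=1
        )
        sets = entity_sets(records, split, "drug")
        fps = {d: morgan_fingerprint(s) for d, s in dicts.drugs.items()}
        for a_name, b_name in itertools.combinations(sets, 2):
            for da in sets[a_name]:
                for db in sets[b_name]:
                    assert tanimoto(fps[da], fps[db]) <= threshold

    @pytest.mark.parametrize("threshold", [0.50, 0.60, 0.70])
    def test_protein_axis_no_cross_subset_identity_above_threshold(
        self, toy_benchmark, threshold
    ):
        from dtakit.audit import global_identity

        records, dicts = toy_benchmark
        split = make_similarity_cold_split(
            records, dicts, "protein", threshold, seed=1
        )
        sets = entity_sets(records, split, "protein")
        for a_name, b_name in itertools.combinations(sets, 2):
            for pa in sets[a_name]:
                for pb in sets[b_name]:
                    assert (
                        global_identity(dicts.proteins[pa], dicts.proteins[pb])
                        <= threshold
                    )

    def test_partition_and_determinism(self, toy_benchmark):
        records, dicts = toy_benchmark
        a = make_similarity_cold_split(records, dicts, "drug", 0.4, seed=3)
        b = make_similarity_cold_split(records, dicts, "drug", 0.4, seed=3)
        a.validate_partition(len(records))
        assert a.to_dict() == b.to_dict()
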