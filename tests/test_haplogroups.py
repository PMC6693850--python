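import numpy as np
import pytest

import mitotrace as mt
from mitotrace.haplotypes import DistanceMatrix

from oracles import table_from


def dm_from_seqs(table):
    return mt.pairwise_distances(table)


def planted_matrix():
    """Two mains 60+ apart; main 1 split into two subgroups 8 apart.

    Haplotype layout (ids a, b, c, d):
      a, b  — subgroup at distance 2 from each other; a is closest to main 2
      c     — second subgroup, 8 from a, 9 from b
      d     — the other main, 60 from a, 61 from b, 62 from c
    """
    ids = ["a", "b", "c", "d"]
    mat = np.array(
        [
            [0, 2, 8, 60],
            [2, 0, 9, 61],
            [8, 9, 0, 62],
            [60, 61, 62, 0],
        ]
    )
    return DistanceMatrix(ids, mat)


class TestClusterByThreshold:
    def test_all_within_threshold_single_component(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 3], [3, 0]]))
        assert mt.cluster_by_threshold(dm, 5) == [{"a", "b"}]

    def test_two_clusters_separated_by_51(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 51], [51, 0]]))
        comps = mt.cluster_by_threshold(dm, 50)
        assert sorted(map(sorted, comps)) == [["a"], ["b"]]

    def test_single_linkage_chains(self):
        mat = np.array([[0, 50, 100], [50, 0, 50], [100, 50, 0]])
        dm = DistanceMatrix(["A", "B", "C"], mat)
        assert mt.cluster_by_threshold(dm, 50) == [{"A", "B", "C"}]

    def test_against_bruteforce_components(self, rng):
        """Single-linkage equals reachability over <=threshold edges."""
        for _ in range(30):
            n = int(rng.integers(2, 9))
            seqs = list({
                "".join(rng.choice(list("ACGT"), size=10)) for _ in range(n)
            })
            table = table_from(seqs)
            dm = dm_from_seqs(table)
            t = int(rng.integers(0, 6))
            comps = mt.cluster_by_threshold(dm, t)
            # brute force: transitive closure over <=t links to a fixed point
            reach = {i: {i} for i in range(len(seqs))}
            changed = True
            while changed:
                changed = False
                for i in range(len(seqs)):
                    new = set(reach[i])
                    for j in range(len(seqs)):
                        if dm.matrix[i, j] <= t:
                            new |= reach[j]
                    if new != reach[i]:
                        reach[i] = new
                        changed = True
            expected = {frozenset(dm.ids[j] for j in reach[i])
                        for i in range(len(seqs))}
            assert {frozenset(c) for c in comps} == expected


class TestAssignNames:
    def test_planted_example_labels(self):
        dm = planted_matrix()
        main_partition = [{"a", "b", "c"}, {"d"}]
        sub_partitions = {0: [{"a", "b"}, {"c"}], 1: [{"d"}]}
        counts = {"a": 3, "b": 2, "c": 1, "d": 1}
        seqs = {"a": "AAAA", "b": "AAAC", "c": "AACC", "d": "CCCC"}
        assignment = mt.assign_names(
            dm, main_partition, sub_partitions, counts, seqs
        )
        labels = {h: assignment.label(h) for h in "abcd"}
        assert labels == {"a": "1A1", "b": "1A2", "c": "1B1", "d": "2A1"}

    def test_too_many_subgroups_rejected(self):
        ids = [f"h{i}" for i in range(27)]
        mat = np.zeros((27, 27), dtype=int)
        for i in range(27):
            for j in range(27):
                if i != j:
                    mat[i, j] = 10  # all mutually > sub threshold
        dm = DistanceMatrix(ids, mat)
        subs = {0: [{h} for h in ids]}
        with pytest.raises(ValueError, match="subgroups"):
            mt.assign_names(dm, [set(ids)], subs,
                            {h: 1 for h in ids}, {h: h for h in ids})


class TestClassify:
    def test_single_haplotype_gets_1a1(self):
        table = table_from(["ACGT"])
        assignment = mt.classify(table, dm_from_seqs(table))
        assert assignment.label("H01") == "1A1"

    def test_two_far_haplotypes_two_mains(self):
        a = "A" * 100
        b = "A" * 40 + "C" * 60  # distance 60 > 50
        table = table_from([a, b])
        assignment = mt.classify(table, dm_from_seqs(table))
        assert sorted(
            assignment.label(h) for h in ["H01", "H02"]
        ) == ["1A1", "2A1"]

    def test_close_chain_all_one_subgroup(self):
        seqs = ["AAAAAAAA", "AAAAAAAT", "AAAAAATT", "AAAAATTT"]
        table = table_from(seqs)
        assignment = mt.classify(table, dm_from_seqs(table))
        labels = [assignment.label(h) for h in table.ids]
        assert all(lab.startswith("1A") for lab in labels)
        assert sorted(lab[2] for lab in labels) == ["1", "2", "3", "4"]

    def test_invalid_thresholds_rejected(self):
        table = table_from(["AAAA", "AATT"])
        dm = dm_from_seqs(table)
        with pytest.raises(ValueError):
            mt.classify(table, dm, main_threshold=5, sub_threshold=5)
        with pytest.raises(ValueError):
            mt.classify(table, dm, main_threshold=0, sub_threshold=0)

    def test_recovers_planted_structure(self, small_pipeline):
        """Planted mains and subgroups are recovered exactly."""
        masked, table, dm, meta, truth = small_pipeline
        assignment = mt.classify(table, dm)
        seq_to_pipeline = {h.key: h.haplotype_id for h in table.haplotypes}

        def translate(planted_part):
            return {
                frozenset(
                    seq_to_pipeline[
                        next(x for x in truth.haplotypes if x.hap_id == hid)
                        .sequence.tobytes().decode()
                    ]
                    for hid in group
                )
                for group in planted_part
            }

        assert {
            frozenset(g) for g in assignment.main_partition()
        } == translate(truth.planted_main_partition())
        assert {
            frozenset(g) for g in assignment.subgroup_partition()
        } == translate(truth.planted_subgroup_partition())

    def test_order_invariance(self, rng):
        seqs = list({
            "".join(rng.choice(list("ACGT"), size=80)) for _ in range(8)
        })
        table = table_from(seqs)
        assignment1 = mt.classify(table, dm_from_seqs(table), 30, 5)
        by_seq1 = {
            h.key: assignment1.label(h.haplotype_id) for h in table.haplotypes
        }
        perm = list(rng.permutation(len(seqs)))
        table2 = table_from([seqs[i] for i in perm])
        assignment2 = mt.classify(table2, dm_from_seqs(table2), 30, 5)
        by_seq2 = {
            h.key: assignment2.label(h.haplotype_id) for h in table2.haplotypes
        }
        assert by_seq1 == by_seq2

    def test_raising_main_threshold_only_merges(self, rng):
        for _ in range(10):
            seqs = list({
                "".join(rng.choice(list("ACGT"), size=60)) for _ in range(7)
            })
            table = table_from(seqs)
            dm = dm_from_seqs(table)
            low = {frozenset(c) for c in mt.cluster_by_threshold(dm, 10)}
            high = {frozenset(c) for c in mt.cluster_by_threshold(dm, 25)}
            # every low-threshold cluster is contained in one high cluster
            for c in low:
                assert any(c <= h for h in high)

    def test_separation_invariants_hold_on_output(self, small_pipeline):
        masked, table, dm, meta, truth = small_pipeline
        assignment = mt.classify(table, dm)
        idx = {h: i for i, h in enumerate(dm.ids)}
        mains = assignment.main_partition()
        for i, ga in enumerate(mains):
            for gb in mains[i + 1:]:
                d = min(dm.matrix[idx[a], idx[b]] for a in ga for b in gb)
                assert d > 50
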