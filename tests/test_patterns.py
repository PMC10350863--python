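import numpy as np
import pytest

import repeatphylo as rp
from repeatphylo.patterns import pattern_label


def contig(cid, sp, seq="ACGTACGTACGTACGT", abundance=0.0):
    return rp.RepeatContig(cid, sp, seq, abundance)


def hit(q, s):
    return rp.SimilarityHit(
        query_id=q, subject_id=s, identity=0.9, aln_length=16,
        query_span=(1, 16), subject_span=(1, 16), score=12.0,
    )


def make_matrix(rows, species):
    return rp.PresenceMatrix(
        class_ids=list(range(len(rows))),
        species=list(species),
        presence=np.array(rows, dtype=bool),
        sizes=np.ones(len(rows), dtype=int),
    )


class TestBuildClasses:
    def test_connected_components(self):
        contigs = [contig(f"S__c{i}", "S") for i in range(1, 5)]
        classes = rp.build_classes(
            contigs, [hit("S__c1", "S__c2"), hit("S__c2", "S__c3")]
        )
        parts = sorted(sorted(c.member_ids) for c in classes)
        assert parts == [["S__c1", "S__c2", "S__c3"], ["S__c4"]]

    def test_no_hits_gives_singletons(self):
        contigs = [contig(f"S__c{i}", "S") for i in range(5)]
        classes = rp.build_classes(contigs, [])
        assert len(classes) == 5
        assert all(c.size == 1 for c in classes)

    def test_complete_graph_pools_species(self):
        contigs = [contig(f"{sp}__c{i}", sp) for i, sp in
                   enumerate(["A", "A", "B", "B", "C", "C"])]
        ids = [c.contig_id for c in contigs]
        hits = [hit(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        (cls,) = rp.build_classes(contigs, hits)
        assert cls.size == 6
        assert cls.species_set == {"A", "B", "C"}

    def test_unknown_id_in_hit_rejected(self):
        with pytest.raises(ValueError, match="unknown contig id"):
            rp.build_classes([contig("S__c1", "S")], [hit("S__c1", "S__zz")])

    def test_partition_invariant_to_input_order(self, rng):
        contigs = [contig(f"S__c{i}", "S") for i in range(8)]
        hits = [hit("S__c0", "S__c1"), hit("S__c1", "S__c2"),
                hit("S__c4", "S__c5"), hit("S__c6", "S__c7")]
        ref = sorted(sorted(c.member_ids) for c in rp.build_classes(contigs, hits))
        for _ in range(5):
            c2 = list(contigs)
            h2 = list(hits)
            rng.shuffle(c2)
            rng.shuffle(h2)
            got = sorted(sorted(c.member_ids) for c in rp.build_classes(c2, h2))
            assert got == ref

    def test_classes_partition_the_contig_set(self):
        contigs = [contig(f"S__c{i}", "S") for i in range(6)]
        classes = rp.build_classes(contigs, [hit("S__c0", "S__c3")])
        members = [cid for c in classes for cid in c.member_ids]
        assert sorted(members) == sorted(c.contig_id for c in contigs)


class TestFilterClasses:
    def make_class(self, n, abundance=0.0, cid=0):
        members = frozenset(f"A__c{cid}_{i}" for i in range(n))
        return rp.RepeatClass(
            class_id=cid, member_ids=members, species_set=frozenset({"A"}),
            total_abundance_by_species={"A": abundance},
        )

    def test_minimum_size_five_is_inclusive(self):
        four, five = self.make_class(4, cid=0), self.make_class(5, cid=1)
        assert rp.filter_classes([four, five]) == [five]

    def test_abundance_threshold_applied_per_species(self):
        low = self.make_class(5, abundance=5e-5, cid=0)
        ok = self.make_class(5, abundance=2e-4, cid=1)
        assert rp.filter_classes([low, ok]) == [ok]

    def test_abundance_test_skipped_when_unknown(self):
        classes = [self.make_class(1, cid=i) for i in range(3)]
        assert rp.filter_classes(classes, min_size=1) == classes

    def test_monotone_in_min_size(self):
        classes = [self.make_class(n, cid=n) for n in range(1, 8)]
        sizes = [len(rp.filter_classes(classes, min_size=k)) for k in range(1, 9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_min_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            rp.filter_classes([], min_size=0)


class TestPresenceMatrix:
    def classes_for(self, patterns):
        out = []
        for k, pat in enumerate(patterns):
            out.append(rp.RepeatClass(
                class_id=k,
                member_ids=frozenset(f"{sp}__c{k}" for sp in pat),
                species_set=frozenset(pat),
                total_abundance_by_species={sp: 0.0 for sp in pat},
            ))
        return out

    def test_rows_follow_species_order(self):
        classes = self.classes_for([{"A", "B"}, {"A"}, {"A", "B", "C"}])
        m = rp.presence_matrix(classes, ["A", "B", "C"])
        assert m.presence.tolist() == [
            [True, True, False], [True, False, False], [True, True, True]
        ]

    def test_empty_class_list_gives_zero_rows(self):
        m = rp.presence_matrix([], ["A", "B"])
        assert m.presence.shape == (0, 2)

    def test_species_missing_from_order_rejected(self):
        classes = self.classes_for([{"A", "D"}])
        with pytest.raises(ValueError, match="D"):
            rp.presence_matrix(classes, ["A", "B", "C"])


class TestTabulatePatterns:
    def test_hand_tally(self):
        m = make_matrix(
            [[1, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 1]],
            "ABCD",
        )
        table = rp.tabulate_patterns(m)
        got = dict(zip(table["pattern"], table["count"]))
        assert got == {"A": 2, "A+B": 1, "A+B+C+D": 1}
        props = dict(zip(table["pattern"], table["proportion"]))
        assert props == {"A": 0.5, "A+B": 0.25, "A+B+C+D": 0.25}

    def test_all_full_rows_collapse_to_one_pattern(self):
        m = make_matrix([[1, 1, 1]] * 4, "ABC")
        table = rp.tabulate_patterns(m)
        assert len(table) == 1
        assert table.loc[0, "proportion"] == 1.0

    def test_all_fifteen_subsets_of_four_species(self):
        """An input realizing every non-empty species subset once yields
        all 15 patterns, each at proportion 1/15."""
        from itertools import combinations

        rows = []
        for r in range(1, 5):
            for combo in combinations(range(4), r):
                row = [False] * 4
                for j in combo:
                    row[j] = True
                rows.append(row)
        table = rp.tabulate_patterns(make_matrix(rows, "ABCD"))
        assert len(table) == 15
        assert set(table["count"]) == {1}
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_counts_sum_to_retained_classes(self, rng):
        rows = rng.random((30, 4)) < 0.5
        rows = rows[rows.any(axis=1)]
        table = rp.tabulate_patterns(make_matrix(rows.tolist(), "ABCD"))
        assert table["count"].sum() == len(rows)
        assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-9)


class TestRankAbundance:
    def test_sorted_descending(self):
        out = rp.rank_abundance({"x": 0.03, "y": 0.10, "z": 0.01})
        assert [k for k, _ in out] == ["y", "x", "z"]

    def test_ties_broken_by_label(self):
        out = rp.rank_abundance({"b": 0.1, "a": 0.1, "c": 0.1})
        assert [k for k, _ in out] == ["a", "b", "c"]

    def test_empty_input(self):
        assert rp.rank_abundance({}) == []

    def test_accepts_library(self):
        lib = rp.RepeatLibrary("S", [
            rp.RepeatContig("c1", "S", "ACGT", 0.02),
            rp.RepeatContig("c2", "S", "ACGT", 0.08),
        ])
        assert [k for k, _ in rp.rank_abundance(lib)] == ["c2", "c1"]
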