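from itertools import combinations

import numpy as np
import pytest

import repeatphylo as rp

from _oracles import dollo_min_losses, rf_distance_bruteforce
from test_patterns import make_matrix
from test_tree import random_binary_tree


class TestRfDistance:
    def test_identical_quartets_are_zero(self, quartet_tree):
        other = rp.read_newick("((A:2,B:2):2,(C:2,D:2):2);")
        assert rp.rf_distance(quartet_tree, other) == 0

    def test_conflicting_quartets_are_two(self, quartet_tree):
        other = rp.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rp.rf_distance(quartet_tree, other) == 2

    def test_caterpillar_cherry_swap_matches_split_enumeration(self):
        t1 = rp.read_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")
        t2 = rp.read_newick("((((A:1,C:1):1,B:1):1,D:1):1,E:1);")
        assert rp.rf_distance(t1, t2) == rf_distance_bruteforce(t1, t2)
        assert rp.rf_distance(t1, t2) > 0

    def test_leaf_set_mismatch_rejected(self, quartet_tree):
        other = rp.read_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            rp.rf_distance(quartet_tree, other)

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            t1 = random_binary_tree(n, rng)
            t2 = random_binary_tree(n, rng)
            assert rp.rf_distance(t1, t2) == rf_distance_bruteforce(t1, t2)

    def test_metric_properties_on_quartets_and_quintets(self, rng):
        trees = [random_binary_tree(5, rng) for _ in range(6)]
        for a in trees:
            assert rp.rf_distance(a, a) == 0
        for a, b in combinations(trees, 2):
            assert rp.rf_distance(a, b) == rp.rf_distance(b, a)
        for a, b in combinations(trees, 2):
            for c in trees:
                assert rp.rf_distance(a, b) <= (
                    rp.rf_distance(a, c) + rp.rf_distance(c, b)
                )


class TestDolloCost:
    def test_clade_costs_nothing(self):
        tree = rp.read_newick("(((A:1,B:1):1,C:1):1,D:1);")
        assert rp.dollo_cost({"A", "B"}, tree) == 0

    def test_non_sister_pair_on_quartet_costs_two(self, quartet_tree):
        assert rp.dollo_cost({"A", "C"}, quartet_tree) == 2

    def test_full_and_singleton_cost_nothing(self, quartet_tree):
        assert rp.dollo_cost({"A", "B", "C", "D"}, quartet_tree) == 0
        assert rp.dollo_cost({"C"}, quartet_tree) == 0

    def test_three_of_four_costs_one(self, quartet_tree):
        assert rp.dollo_cost({"A", "B", "C"}, quartet_tree) == 1

    def test_empty_or_unknown_pattern_rejected(self, quartet_tree):
        with pytest.raises(ValueError):
            rp.dollo_cost(set(), quartet_tree)
        with pytest.raises(ValueError, match="unknown"):
            rp.dollo_cost({"A", "Z"}, quartet_tree)

    def test_matches_exhaustive_labeling_oracle(self, rng):
        """Single-gain minimum-loss counts agree with brute-force
        enumeration of all gain/loss placements on random trees."""
        for _ in range(15):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(n, rng)
            leaves = [t.name for t in tree.tips()]
            for _ in range(20):
                k = int(rng.integers(1, n + 1))
                pattern = set(rng.choice(leaves, size=k, replace=False))
                assert rp.dollo_cost(pattern, tree) == dollo_min_losses(
                    pattern, tree
                )

    def test_zero_cost_iff_clade(self, rng):
        for _ in range(10):
            tree = random_binary_tree(6, rng)
            leaves = [t.name for t in tree.tips()]
            clades = set()
            for node in tree.postorder(include_self=True):
                clades.add(frozenset(t.name for t in node.tips())
                           if not node.is_tip() else frozenset([node.name]))
            for _ in range(20):
                k = int(rng.integers(1, 7))
                pattern = frozenset(rng.choice(leaves, size=k, replace=False))
                assert (rp.dollo_cost(pattern, tree) == 0) == (pattern in clades)


class TestFlagDiscordant:
    def test_quartet_examples(self, quartet_tree):
        m = make_matrix(
            [[1, 0, 1, 0],   # {A,C}: non-sisters -> discordant
             [1, 1, 0, 0],   # {A,B}: sister clade -> concordant
             [1, 1, 1, 0],   # {A,B,C}: not a clade -> discordant
             [0, 0, 1, 0],   # singleton -> never discordant
             [1, 1, 1, 1]],  # full set -> never discordant
            "ABCD",
        )
        report = rp.flag_discordant(m, quartet_tree)
        assert list(report["discordant"]) == [True, False, True, False, False]
        assert list(report["dollo_losses"]) == [2, 0, 1, 0, 0]

    def test_species_mismatch_rejected(self, quartet_tree):
        m = make_matrix([[1, 1, 1]], "ABC")
        with pytest.raises(ValueError, match="do not match"):
            rp.flag_discordant(m, quartet_tree)

    def test_agrees_with_dollo_oracle_on_random_trees(self, rng):
        """Discordance == "needs at least one Dollo loss" for multi-
        species non-full patterns, against the exhaustive oracle."""
        for _ in range(8):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(n, rng)
            leaves = sorted(t.name for t in tree.tips())
            rows, expected = [], []
            for _ in range(25):
                k = int(rng.integers(1, n + 1))
                chosen = set(rng.choice(leaves, size=k, replace=False))
                rows.append([sp in chosen for sp in leaves])
                oracle_losses = dollo_min_losses(chosen, tree)
                expected.append(len(chosen) >= 2 and oracle_losses >= 1)
            m = make_matrix(rows, leaves)
            report = rp.flag_discordant(m, tree)
            assert list(report["discordant"]) == expected


class TestPairTables:
    def test_exclusive_tally(self):
        m = make_matrix([[1, 1, 0], [1, 1, 0], [1, 0, 1]], "ABC")
        table = rp.pairwise_exclusive_shared(m)
        got = {(r.species_a, r.species_b): r.count for r in table.itertuples()}
        assert got == {("A", "B"): 2, ("A", "C"): 1, ("B", "C"): 0}

    def test_no_two_species_patterns_gives_zeros(self):
        m = make_matrix([[1, 0, 0], [1, 1, 1]], "ABC")
        table = rp.pairwise_exclusive_shared(m)
        assert set(table["count"]) == {0}

    def test_all_six_pairs_of_four_species(self):
        rows = []
        for pair in combinations(range(4), 2):
            row = [False] * 4
            for j in pair:
                row[j] = True
            rows.append(row)
        table = rp.pairwise_exclusive_shared(make_matrix(rows, "ABCD"))
        assert len(table) == 6
        assert set(table["count"]) == {1}

    def test_shared_any_counts_supersets(self):
        m = make_matrix([[1, 1, 1], [1, 1, 0]], "ABC")
        table = rp.pairwise_shared_any(m)
        got = {(r.species_a, r.species_b): r.count for r in table.itertuples()}
        assert got == {("A", "B"): 2, ("A", "C"): 1, ("B", "C"): 1}
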