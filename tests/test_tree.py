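import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

import repeatphylo as rp
from repeatphylo.distance import DistanceMatrix

from _oracles import nontrivial_splits


def random_binary_tree(n_leaves, rng, min_len=0.1, max_len=2.0):
    """Random topology by sequential leaf attachment, U(min,max) lengths."""
    names = [f"t{i}" for i in range(n_leaves)]
    tree = TreeNode.read(io.StringIO(f"({names[0]}:1,{names[1]}:1);"))
    for name in names[2:]:
        edges = [n for n in tree.traverse(include_self=False)]
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        parent.remove(target)
        joint = TreeNode(length=1.0)
        leaf = TreeNode(name=name, length=1.0)
        joint.extend([target, leaf])
        parent.append(joint)
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(min_len, max_len))
    return tree


def path_length_matrix(tree) -> DistanceMatrix:
    dm = tree.tip_tip_distances()
    return DistanceMatrix(labels=[str(x) for x in dm.ids],
                          values=np.array(dm.data))


class TestNeighborJoining:
    def test_additive_quartet_recovered_with_exact_lengths(self):
        source = rp.read_newick("((A:1.0,B:2.0):1.0,(C:3.0,D:1.0):1.0);")
        dm = path_length_matrix(source)
        tree = rp.neighbor_joining(dm)
        assert nontrivial_splits(tree) == {frozenset("AB")} or \
            nontrivial_splits(tree) == {frozenset("CD")}
        # path lengths reproduce the input exactly
        out = path_length_matrix(tree)
        order = [out.labels.index(x) for x in dm.labels]
        assert np.allclose(out.values[np.ix_(order, order)], dm.values,
                           atol=1e-9)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(labels=list("ABC"),
                            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = rp.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert lengths["B"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert lengths["C"] == pytest.approx(0.5 * (4 + 5 - 3))

    def test_equidistant_four_taxa_gets_zero_internal_branch(self):
        values = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=list("ABCD"), values=values)
        tree = rp.neighbor_joining(dm)
        internal = [n.length for n in tree.traverse(include_self=False)
                    if not n.is_tip()]
        assert internal == pytest.approx([0.0])
        # deterministic tie rule: repeated runs give the identical tree
        assert rp.to_newick(tree) == rp.to_newick(rp.neighbor_joining(dm))

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError, match="3 taxa"):
            rp.neighbor_joining(dm)

    def test_consistency_on_random_additive_matrices(self, rng):
        """NJ recovers the generating topology and its path lengths from
        exact path-length matrices (the Saitou-Nei consistency
        guarantee), here on 30 random 4-8 leaf trees."""
        for _ in range(30):
            n = int(rng.integers(4, 9))
            source = random_binary_tree(n, rng)
            dm = path_length_matrix(source)
            tree = rp.neighbor_joining(dm)
            assert nontrivial_splits(tree) == nontrivial_splits(source)
            out = path_length_matrix(tree)
            order = [out.labels.index(x) for x in dm.labels]
            assert np.allclose(out.values[np.ix_(order, order)], dm.values,
                               atol=1e-9)

    def test_agrees_with_scikit_bio_on_noisy_matrices(self, rng):
        """Cross-check against an independent NJ implementation on
        non-additive (noisy) inputs: same unrooted topology."""
        for _ in range(10):
            n = int(rng.integers(4, 8))
            source = random_binary_tree(n, rng)
            dm = path_length_matrix(source)
            noise = rng.uniform(0.98, 1.02, size=dm.values.shape)
            noisy = dm.values * (noise + noise.T) / 2
            np.fill_diagonal(noisy, 0.0)
            mine = rp.neighbor_joining(DistanceMatrix(dm.labels, noisy))
            theirs = skbio_nj(SkbioDM(noisy, dm.labels))
            assert nontrivial_splits(mine) == nontrivial_splits(theirs)


class TestMidpointRoot:
    def test_longest_path_split_in_half(self):
        tree = rp.read_newick("((A:1,B:1):1,(C:5,D:1):0);")
        rooted = rp.midpoint_root(tree)
        # longest path is B..C (or A..C) = 7; midpoint 3.5 from C
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert max(depths.values()) == pytest.approx(3.5)
        assert depths["C"] == pytest.approx(3.5)

    def test_balanced_tree_rooted_at_center(self):
        tree = rp.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = rp.midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert all(d == pytest.approx(2.0) for d in depths.values())

    def test_two_leaves(self):
        tree = rp.read_newick("(A:1,B:3);")
        rooted = rp.midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_zero_length_tree_rejected(self):
        tree = rp.read_newick("((A:0,B:0):0,C:0);")
        with pytest.raises(ValueError, match="midpoint"):
            rp.midpoint_root(tree)

    def test_topology_and_path_lengths_preserved(self, rng):
        for _ in range(10):
            source = random_binary_tree(int(rng.integers(4, 9)), rng)
            before = path_length_matrix(source)
            rooted = rp.midpoint_root(source)
            assert nontrivial_splits(rooted) == nontrivial_splits(source)
            after = path_length_matrix(rooted)
            order = [after.labels.index(x) for x in before.labels]
            assert np.allclose(after.values[np.ix_(order, order)],
                               before.values, atol=1e-9)


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        tree = rp.read_newick("((A:1.5,B:2.25):0.5,(C:3.0,D:1.0):0.5);")
        path = tmp_path / "t.nwk"
        rp.write_newick(tree, path)
        back = rp.read_newick(path)
        assert nontrivial_splits(back) == nontrivial_splits(tree)
        assert {t.name: t.length for t in back.tips()} == {
            t.name: t.length for t in tree.tips()
        }
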