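import numpy as np
import pytest

from bqpipe.network_distance import DistanceMatrix
from bqpipe.synthetic_data import simulate_species_tree
from bqpipe.trees import (
    neighbor_join,
    parse_newick,
    read_newick,
    resolve_polytomies,
    robinson_foulds,
    root_to_tip_lengths,
    shared_split_fraction,
    splits,
    write_newick,
)


def pairwise_path_distances(tree):
    """Independent oracle: tip-to-tip distances via root paths."""
    paths = {}

    def walk(node, acc):
        acc = acc + ([node] if node.parent is not None else [])
        if node.is_tip:
            paths[node.label] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    labels = sorted(paths)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            shared = 0
            for a, b in zip(pi, pj):
                if a is b:
                    shared += 1
                else:
                    break
            d = sum(e.length for e in pi[shared:]) + sum(e.length for e in pj[shared:])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


class TestNeighborJoin:
    def test_four_taxon_worked_example(self):
        # additive distances from the tree ((A:1,B:2)-2-(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_join(DistanceMatrix(labels, d))
        assert splits(tree) == {frozenset({"C", "D"})}
        lengths = {t.label: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        # recovered tip-to-tip distances reproduce the input exactly
        rec = pairwise_path_distances(tree)
        assert np.allclose(rec.reorder(labels).values, d)

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_join(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.label: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_zero_matrix_star(self):
        tree = neighbor_join(DistanceMatrix(["A", "B", "C"], np.zeros((3, 3))))
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert all(t.length == 0 for t in tree.tips())

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_join(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (10, 2), (12, 3), (12, 4)])
    def test_recovers_additive_topology(self, n, seed):
        # NJ is consistent on additive distances: splits must match exactly
        true_tree = simulate_species_tree(n, seed)
        dm = pairwise_path_distances(true_tree)
        recovered = neighbor_join(dm)
        assert splits(recovered) == splits(true_tree)
        rec = pairwise_path_distances(recovered)
        assert np.allclose(rec.values, dm.reorder(rec.labels).values, atol=1e-9)

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        a = neighbor_join(DistanceMatrix(["A", "B", "C", "D"], d)).to_newick()
        b = neighbor_join(DistanceMatrix(["A", "B", "C", "D"], d)).to_newick()
        assert a == b


class TestNewickIO:
    def test_two_tip_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2):0;\n")
        tree = read_newick(p)
        assert sorted(tree.tip_labels) == ["A", "B"]

    def test_roundtrip_random_trees(self, tmp_path):
        for seed in range(5):
            tree = simulate_species_tree(9, seed)
            p = write_newick(tree, tmp_path / f"t{seed}.nwk")
            back = read_newick(p)
            assert splits(back) == splits(tree)
            r1, r2 = root_to_tip_lengths(tree), root_to_tip_lengths(back)
            for tip in r1:
                assert r1[tip] == pytest.approx(r2[tip], abs=1e-9)

    def test_missing_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing branch lengths"):
            tree = parse_newick("((A,B),C);")
        assert all(t.length == 0 for t in tree.tips())

    def test_unbalanced_parentheses(self):
        with pytest.raises(ValueError, match="parse error"):
            parse_newick("((A:1,B:2:0;")


class TestSplits:
    def test_four_tip_single_split(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        assert splits(tree) == {frozenset({"C", "D"})}

    def test_star_tree_no_splits(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1):0;")
        assert splits(tree) == set()

    @pytest.mark.parametrize("n", range(5, 11))
    def test_binary_tree_split_count(self, n):
        tree = simulate_species_tree(n, seed=n)
        assert len(splits(tree)) == n - 3


class TestSharedSplitFraction:
    def test_identical_trees_100(self):
        tree = simulate_species_tree(10, seed=5)
        cmp_ = shared_split_fraction(tree, tree)
        assert cmp_.shared_pct == 100.0
        assert cmp_.rf_distance == 0

    def test_conflicting_quartets_0(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1):0;")
        cmp_ = shared_split_fraction(t1, t2)
        assert cmp_.shared_pct == 0.0

    def test_one_nni_changes_one_split(self):
        # one NNI across the (A,B)|(C,D) edge alters exactly one split
        t1 = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1):0;")
        t2 = parse_newick("(((A:1,(C:1,D:1):1):1,B:1):1,(E:1,F:1):1):0;")
        n = 6
        cmp_ = shared_split_fraction(t1, t2)
        assert cmp_.shared_pct == pytest.approx((n - 4) / (n - 3) * 100)

    def test_rf_identity_cross_check(self):
        t1 = simulate_species_tree(10, seed=6)
        t2 = simulate_species_tree(10, seed=7)
        s1, s2 = splits(t1), splits(t2)
        assert robinson_foulds(t1, t2) == len(s1) + len(s2) - 2 * len(s1 & s2)

    def test_tip_set_mismatch(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1):0;")
        with pytest.raises(ValueError):
            shared_split_fraction(t1, t2)


class TestRootToTip:
    def test_hand_example(self):
        tree = parse_newick("((A:1,B:2):3):0;")
        lengths = root_to_tip_lengths(tree)
        assert lengths == pytest.approx({"A": 4, "B": 5})

    def test_ultrametric_all_equal(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        lengths = root_to_tip_lengths(tree)
        assert len(set(lengths.values())) == 1

    def test_matches_exhaustive_path_sum(self):
        tree = simulate_species_tree(12, seed=9)
        lengths = root_to_tip_lengths(tree)

        def brute(node, acc, out):
            acc += node.length if node.parent is not None else 0
            if node.is_tip:
                out[node.label] = acc
            for c in node.children:
                brute(c, acc, out)

        expected = {}
        brute(tree.root, 0.0, expected)
        for tip, d in expected.items():
            assert lengths[tip] == pytest.approx(d)

    def test_unrooted_rejected(self):
        tree = parse_newick("(A:1,B:1,C:1):0;")
        tree.rooted = False
        with pytest.raises(ValueError):
            root_to_tip_lengths(tree)


def test_resolve_polytomies_makes_binary():
    tree = parse_newick("(A:1,B:1,C:1,D:1,E:1):0;")
    resolved = resolve_polytomies(tree)
    assert resolved.is_binary() or len(resolved.root.children) == 2
    assert sorted(resolved.tip_labels) == ["A", "B", "C", "D", "E"]
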