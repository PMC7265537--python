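from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import distance as ssd

from bqpipe.metabolic_network import KoReactionCompoundMap, build_network
from bqpipe.network_distance import (
    DistanceMatrix,
    adkins_canberra,
    canberra,
    distance_matrix,
    jaccard_distance,
    read_phylip_lower,
    weighted_jaccard,
    write_phylip_lower,
)

nonneg_vectors = st.lists(
    st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=20
)


class TestJaccard:
    def test_worked_example(self):
        assert jaccard_distance({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_identity(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint(self):
        assert jaccard_distance({"a"}, {"b"}) == 1.0

    def test_both_empty(self):
        assert jaccard_distance(set(), set()) == 0.0


class TestWeightedJaccard:
    def test_worked_example(self):
        # 1 - (1+1+0)/(2+2+1)
        assert weighted_jaccard([1, 2, 0], [2, 1, 1]) == pytest.approx(0.6)

    def test_identity(self):
        assert weighted_jaccard([1, 2, 3], [1, 2, 3]) == 0.0

    def test_binary_equals_unweighted(self):
        x, y = [1, 1, 1, 0], [0, 1, 1, 1]  # sets {a,b,c}, {b,c,d}
        assert weighted_jaccard(x, y) == pytest.approx(
            jaccard_distance({"a", "b", "c"}, {"b", "c", "d"})
        )

    def test_binary_equivalence_exhaustive_5(self):
        universe = list(range(5))
        for bits_x, bits_y in product(product((0, 1), repeat=5), repeat=2):
            sx = {u for u, b in zip(universe, bits_x) if b}
            sy = {u for u, b in zip(universe, bits_y) if b}
            assert weighted_jaccard(list(bits_x), list(bits_y)) == pytest.approx(
                jaccard_distance(sx, sy)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_jaccard([1, 2], [1, 2, 3])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weighted_jaccard([-1, 0], [0, 1])

    @given(nonneg_vectors, st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant(self, x, c):
        y = x[::-1]
        assert weighted_jaccard(np.array(x) * c, np.array(y) * c) == pytest.approx(
            weighted_jaccard(x, y), abs=1e-9
        )


class TestCanberra:
    def test_worked_example(self):
        assert canberra([1, 2, 0], [2, 1, 1]) == pytest.approx(5 / 3)

    def test_identity(self):
        assert canberra([1, 2, 0], [1, 2, 0]) == 0.0

    def test_joint_zero_term_skipped(self):
        assert canberra([1, 0], [2, 0]) == pytest.approx(1 / 3)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            assert canberra(x, y) == pytest.approx(ssd.canberra(x, y))

    def test_triangle_inequality(self, rng):
        for _ in range(100):
            x, y, z = rng.random((3, 8)) * 10
            assert canberra(x, z) <= canberra(x, y) + canberra(y, z) + 1e-12

    @given(nonneg_vectors, st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant(self, x, c):
        y = x[::-1]
        assert canberra(np.array(x) * c, np.array(y) * c) == pytest.approx(
            canberra(x, y), abs=1e-9
        )


class TestAdkinsCanberra:
    def test_worked_example(self):
        assert adkins_canberra([1, 2, 0], [2, 1, 1]) == pytest.approx(5 / 9)

    def test_identity(self):
        assert adkins_canberra([1, 2, 3], [1, 2, 3]) == 0.0

    def test_single_active_term(self):
        assert adkins_canberra([1, 0, 0], [0, 0, 0]) == pytest.approx(1.0)

    def test_bounded_unit_interval(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, size=10).astype(float)
            y = rng.integers(0, 4, size=10).astype(float)
            assert 0.0 <= adkins_canberra(x, y) <= 1.0

    def test_nz_zero_warns(self):
        with pytest.warns(UserWarning):
            assert adkins_canberra([0, 0], [0, 0]) == 0.0

    def test_strict_both_mode(self):
        # only position 0 has both nonzero; term sum = 1/3 + 1 -> /1
        assert adkins_canberra([1, 1], [2, 0], nz_mode="both") == pytest.approx(4 / 3)


@given(nonneg_vectors)
@settings(max_examples=50, deadline=None)
def test_metric_axioms_all_measures(x):
    y = x[::-1]
    xv, yv = np.array(x), np.array(y)
    for fn in (weighted_jaccard, canberra, adkins_canberra):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert fn(xv, yv) == pytest.approx(fn(yv, xv))
            assert fn(xv, xv) == 0.0
            assert fn(xv, yv) >= 0.0


def _nets():
    komap = KoReactionCompoundMap(
        ko_to_rn={f"K0000{i}": frozenset({f"R0000{i}"}) for i in range(1, 5)},
        rn_to_cpds={
            "R00001": frozenset({"c1", "c2"}),
            "R00002": frozenset({"c2", "c3"}),
            "R00003": frozenset({"c3", "c4"}),
            "R00004": frozenset({"c1", "c4"}),
        },
    )
    gene_sets = {
        "spA": ["K00001", "K00002"],
        "spB": ["K00002", "K00003"],
        "spC": ["K00003", "K00004", "K00004"],
    }
    return [build_network(sp, ks, komap) for sp, ks in sorted(gene_sets.items())]


class TestDistanceMatrix:
    def test_identical_networks_zero_matrix(self):
        nets = _nets()
        same = [build_network(f"s{i}", ["K1"], KoReactionCompoundMap(
            ko_to_rn={"K1": frozenset({"R1"})},
            rn_to_cpds={"R1": frozenset({"c1", "c2"})})) for i in range(3)]
        dm = distance_matrix(same, measure="adcan")
        assert np.allclose(dm.values, 0)

    @pytest.mark.parametrize("measure", ["jaccard", "wjaccard", "canberra", "adcan"])
    def test_matches_pairwise_calls(self, measure):
        from bqpipe.metabolic_network import node_abundance_vector

        nets = _nets()
        dm = distance_matrix(nets, measure=measure)
        universe = sorted(set().union(*(n.nodes for n in nets)))
        for i, j in combinations(range(3), 2):
            if measure == "jaccard":
                expected = jaccard_distance(nets[i].nodes, nets[j].nodes)
            else:
                vi = node_abundance_vector(nets[i], universe)
                vj = node_abundance_vector(nets[j], universe)
                fn = {"wjaccard": weighted_jaccard, "canberra": canberra,
                      "adcan": adkins_canberra}[measure]
                expected = fn(vi, vj)
            assert dm.values[i, j] == pytest.approx(expected)

    def test_relabeling_permutes_consistently(self):
        nets = _nets()
        dm = distance_matrix(nets)
        perm = ["spC", "spA", "spB"]
        dm2 = distance_matrix([nets[2], nets[0], nets[1]])
        assert np.allclose(dm.reorder(perm).values, dm2.values)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            distance_matrix(_nets()[:2])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestPhylip:
    def test_zero_matrix_format(self, tmp_path):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        p = write_phylip_lower(dm, tmp_path / "d.phy")
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4

    def test_roundtrip(self, tmp_path):
        vals = np.array([[0, 1, 2.5], [1, 0, 3], [2.5, 3, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], vals)
        p = write_phylip_lower(dm, tmp_path / "d.phy")
        back = read_phylip_lower(p)
        assert back.labels == ["A", "B", "C"]
        assert np.allclose(back.values, vals)

    def test_sixteen_species_line_count(self, tmp_path, rng):
        n = 16
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"sp{i:02d}" for i in range(n)], m)
        p = write_phylip_lower(dm, tmp_path / "d.phy")
        assert len(p.read_text().splitlines()) == 17

    def test_duplicate_sanitized_labels_rejected(self, tmp_path):
        dm = DistanceMatrix(
            ["longspeciesname_one", "longspeciesname_two", "x"], np.zeros((3, 3))
        )
        with pytest.raises(ValueError, match="duplicate"):
            write_phylip_lower(dm, tmp_path / "d.phy")

    def test_relaxed_mode_keeps_labels(self, tmp_path):
        dm = DistanceMatrix(
            ["longspeciesname_one", "longspeciesname_two", "x"], np.zeros((3, 3))
        )
        p = write_phylip_lower(dm, tmp_path / "d.phy", relaxed=True)
        assert read_phylip_lower(p).labels[0] == "longspeciesname_one"
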