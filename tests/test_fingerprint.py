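"""Band filtering, binary distances, UPGMA dendrograms, pattern classes."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ambiscan import (
    BandMatrix,
    DistanceMatrix,
    band_distance,
    distance_matrix,
    distinct_patterns,
    filter_bands,
    upgma,
)
from conftest import random_ultrametric


def matrix(rows, sizes=None, strains=None):
    rows = np.asarray(rows, dtype=bool)
    return BandMatrix(
        strain_ids=strains or [f"S{i}" for i in range(rows.shape[0])],
        band_ids=[f"B{j}" for j in range(rows.shape[1])],
        presence=rows,
        band_sizes=sizes,
    )


class TestFilterBands:
    def test_strictly_larger_rule(self):
        m = matrix([[1, 1], [0, 1]], sizes=[1200.0, 500.0])
        out = filter_bands(m, 1000)
        assert out.band_sizes == [1200.0]
        assert out.presence.tolist() == [[True], [False]]

    def test_min_zero_is_identity(self):
        m = matrix([[1, 0], [0, 1]], sizes=[100.0, 200.0])
        out = filter_bands(m, 0)
        assert out.presence.tolist() == m.presence.tolist()

    def test_all_bands_removed_warns(self):
        m = matrix([[1, 1]], sizes=[100.0, 200.0])
        with pytest.warns(UserWarning, match="empty band set"):
            out = filter_bands(m, 5000)
        assert out.presence.shape == (1, 0)

    def test_sizes_required(self):
        with pytest.raises(ValueError):
            filter_bands(matrix([[1, 0]]), 1000)


class TestBandDistance:
    @pytest.mark.parametrize("coefficient", ["jaccard", "dice", "simple_matching"])
    def test_identical_vectors(self, coefficient):
        assert band_distance([1, 0, 1], [1, 0, 1], coefficient) == 0.0

    @pytest.mark.parametrize("coefficient", ["jaccard", "dice"])
    def test_disjoint_nonempty(self, coefficient):
        assert band_distance([1, 1, 0, 0], [0, 0, 1, 1], coefficient) == 1.0

    def test_jaccard_by_hand(self):
        # patterns 1100 vs 1010: one shared band, union of three
        assert band_distance([1, 1, 0, 0], [1, 0, 1, 0], "jaccard") == pytest.approx(2 / 3)

    def test_all_zero_vectors_defined_as_zero_with_warning(self):
        for coefficient in ("jaccard", "dice"):
            with pytest.warns(UserWarning):
                assert band_distance([0, 0], [0, 0], coefficient) == 0.0

    def test_symmetry_and_identity_of_indiscernibles(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.random(15) < 0.5
            b = rng.random(15) < 0.5
            if not a.any() or not b.any():
                continue
            for coefficient in ("jaccard", "dice", "simple_matching"):
                d_ab = band_distance(a, b, coefficient)
                assert d_ab == band_distance(b, a, coefficient)
                assert 0.0 <= d_ab <= 1.0
                if coefficient != "simple_matching":
                    assert (d_ab == 0.0) == bool((a == b).all())


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(ids=["A", "B"], values=np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = upgma(dm)
        depths = tree.leaf_depths()
        assert depths["A"] == pytest.approx(0.2)
        assert depths["B"] == pytest.approx(0.2)

    def test_three_leaves_hand_agglomeration(self):
        dm = DistanceMatrix(
            ids=["A", "B", "C"],
            values=np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]]),
        )
        tree = upgma(dm)
        # ((A,B),C): A,B join at height 1, C at height 3
        assert tree.newick == "((A:1.0,B:1.0):2.0,C:3.0);"

    def test_zero_distance_cherry(self):
        dm = DistanceMatrix(
            ids=["A", "B", "C"],
            values=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]),
        )
        tree = upgma(dm)
        assert "(A:0.0,B:0.0):0.5" in tree.newick

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["A", "B"], values=np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["A", "B"], values=np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(ids=["A"], values=np.zeros((1, 1))))

    def test_output_ultrametric_on_random_matrices(self):
        """All leaves sit at the same depth, within 1e-9, even on
        non-ultrametric random input."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(3, 12))
            raw = rng.random((n, n))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma(DistanceMatrix(ids=[f"L{i}" for i in range(n)], values=d))
            depths = list(tree.leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9

    def test_matches_scipy_average_linkage_cophenetics(self):
        """Independent oracle: scipy's average linkage yields the same
        cophenetic distances on inputs with distinct merge distances."""
        rng = np.random.default_rng(47)
        for _ in range(10):
            n = 8
            raw = rng.random((n, n)) + 0.01
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            ids = [f"L{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(ids=ids, values=d))
            skdm = tree.tree.tip_tip_distances(endpoints=ids)
            mine = np.asarray(skdm.data)
            scipy_coph = squareform(cophenet(linkage(squareform(d), method="average")))
            assert np.allclose(mine, scipy_coph, atol=1e-9)

    def test_recovers_random_ultrametric_trees(self):
        rng = np.random.default_rng(53)
        for _ in range(15):
            n = int(rng.integers(3, 16))
            ids = [f"T{i:02d}" for i in range(n)]
            coph = random_ultrametric(ids, rng)
            tree = upgma(DistanceMatrix(ids=ids, values=coph))
            got = np.asarray(tree.tree.tip_tip_distances(endpoints=ids).data)
            assert np.allclose(got, coph, atol=1e-9)


class TestDistinctPatterns:
    def test_row_classes_and_pairs(self):
        m = matrix([[1, 1, 0], [1, 1, 0], [0, 1, 1]], strains=["a", "b", "c"])
        out = distinct_patterns(m)
        assert out.n_patterns == 2
        assert out.undistinguishable_pairs == [("a", "b")]

    def test_all_distinct(self):
        m = matrix([[1, 0], [0, 1], [1, 1]])
        out = distinct_patterns(m)
        assert out.n_patterns == 3 and out.undistinguishable_pairs == []

    def test_single_strain(self):
        assert distinct_patterns(matrix([[1, 0, 1]])).n_patterns == 1

    def test_invariant_under_permutations(self):
        rng = np.random.default_rng(61)
        rows = rng.random((12, 18)) < 0.5
        base = distinct_patterns(matrix(rows)).n_patterns
        for _ in range(5):
            rp = rng.permutation(12)
            cp = rng.permutation(18)
            shuffled = rows[rp][:, cp]
            assert distinct_patterns(matrix(shuffled)).n_patterns == base


def test_distance_matrix_from_bands():
    m = matrix([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0]], strains=["x", "y", "z"])
    dm = distance_matrix(m, coefficient="jaccard")
    assert dm.values[0, 1] == pytest.approx(2 / 3)
    assert dm.values[0, 2] == 0.0
    assert np.allclose(dm.values, dm.values.T)
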