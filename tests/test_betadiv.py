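"""Raup-Crick null model, Bray-Curtis, UPGMA and the inverse normal transform."""

import io as _io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from ednakit.betadiv import (
    bray_curtis,
    clusters_at,
    inverse_normal_transform,
    raup_crick,
    raup_crick_exact_equiprobable,
    upgma,
)
from ednakit.io import write_newick


def presence(rows: dict[str, str]) -> pd.DataFrame:
    """Rows of '0101' strings to a boolean DataFrame."""
    return pd.DataFrame(
        {unit: [c == "1" for c in bits] for unit, bits in rows.items()}
    ).T.rename(columns=lambda i: f"sp{i}")


class TestRaupCrick:
    def test_identical_rich_sites_score_near_zero(self):
        # duplicated sites in a pool much richer than either site's richness
        bits = "1" * 15 + "0" * 25
        others = "0" * 15 + "1" * 25
        mat = presence({"a": bits, "b": bits, "c": others, "d": others[::-1]})
        d = raup_crick(mat, n_sim=9999, seed=1)
        assert d["a", "b"] < 0.05

    def test_disjoint_sites_score_near_one(self):
        mat = presence({"a": "1" * 10 + "0" * 30, "b": "0" * 30 + "1" * 10})
        d = raup_crick(mat, n_sim=4999, null_model="equiprobable", seed=1)
        assert d["a", "b"] > 0.95

    def test_equiprobable_matches_hypergeometric_closed_form(self):
        # pool S=4, richness a=b=2, full overlap: exact value 1/12
        mat = presence({"a": "1100", "b": "1100"})
        exact = raup_crick_exact_equiprobable(4, 2, 2, 2)
        assert exact == pytest.approx(1 / 12)
        n_sim = 100_000
        d = raup_crick(mat, n_sim=n_sim, null_model="equiprobable", seed=3)
        se = math.sqrt(exact * (1 - exact) / n_sim)
        assert abs(d["a", "b"] - exact) < 3 * se

    def test_invariant_to_taxon_column_permutation(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.random((4, 12)) < 0.4,
            index=list("abcd"), columns=[f"sp{i}" for i in range(12)],
        )
        perm = rng.permutation(mat.columns)
        a = raup_crick(mat, n_sim=999, seed=7)
        b = raup_crick(mat[perm], n_sim=999, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_taxon_site_pairs_set_to_one(self):
        mat = presence({"a": "1100", "b": "0000", "c": "0011"})
        with pytest.warns(UserWarning, match="zero taxa"):
            d = raup_crick(mat, n_sim=99, seed=0)
        assert d["a", "b"] == 1.0 and d["b", "c"] == 1.0

    def test_values_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.random((5, 20)) < 0.3)
        mat.iloc[0] |= True  # avoid an empty unit
        d = raup_crick(mat.astype(bool), n_sim=499, seed=2)
        assert ((d.data >= 0) & (d.data <= 1)).all()
        np.testing.assert_allclose(d.data, d.data.T)


class TestBrayCurtis:
    def test_disjoint_is_one(self):
        mat = pd.DataFrame([[10, 0], [0, 10]], index=["a", "b"])
        assert bray_curtis(mat)["a", "b"] == 1.0

    def test_self_is_zero(self):
        mat = pd.DataFrame([[3, 4, 5], [3, 4, 5]], index=["a", "b"])
        assert bray_curtis(mat)["a", "b"] == 0.0

    def test_worked_example(self):
        mat = pd.DataFrame([[6, 2], [2, 2]], index=["a", "b"])
        assert bray_curtis(mat)["a", "b"] == pytest.approx(1 / 3)

    def test_all_zero_pair_is_an_error(self):
        mat = pd.DataFrame([[0, 0], [0, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(mat)

    def test_matches_scipy_reference(self, rng):
        X = rng.integers(0, 20, (6, 10))
        mat = pd.DataFrame(X)
        expected = squareform(pdist(X, metric="braycurtis"))
        np.testing.assert_allclose(bray_curtis(mat).data, expected, atol=1e-12)

    def test_equals_sorensen_on_presence(self, rng):
        X = (rng.random((5, 15)) < 0.5).astype(int)
        X[:, 0] = 1
        d = bray_curtis(pd.DataFrame(X))
        for j, k in itertools.combinations(range(5), 2):
            a = X[j].sum()
            b = X[k].sum()
            shared = (X[j] & X[k]).sum()
            sorensen = 1 - 2 * shared / (a + b)
            assert d.data[j, k] == pytest.approx(sorensen)


class TestUpgma:
    def test_three_point_hand_agglomeration(self):
        dm = DistanceMatrix(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        tree, merges = upgma(dm)
        assert merges[0][:2] == ("A", "B") and merges[0][2] == 1.0
        assert merges[1][2] == 4.0
        assert write_newick(tree) == "((A:0.5,B:0.5):1.5,C:2);"

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic distances of the output tree equal the input matrix
        dm = DistanceMatrix(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
            ids=list("ABCD"),
        )
        tree, _ = upgma(dm)
        tips = {t.name: t for t in tree.tips()}
        for a, b in itertools.combinations("ABCD", 2):
            assert tips[a].distance(tips[b]) == pytest.approx(dm[a, b])

    def test_tie_broken_lexicographically(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=["C", "A", "B"])
        _, merges = upgma(dm)
        assert merges[0][:2] == ("A", "B")

    def test_matches_exhaustive_reference_on_small_matrices(self, rng):
        # oracle recomputes every between-cluster mean from the original
        # matrix instead of the running-update recurrence
        def reference(D, labels):
            clusters = {lab: [i] for i, lab in enumerate(labels)}
            merges = []
            while len(clusters) > 1:
                best = None
                for la, lb in itertools.combinations(sorted(clusters), 2):
                    d = float(np.mean([
                        D[i, j] for i in clusters[la] for j in clusters[lb]
                    ]))
                    cand = (d, la, lb)
                    if best is None or cand < best:
                        best = cand
                d, la, lb = best
                clusters[min(la, lb)] = clusters.pop(la) + clusters.pop(lb)
                merges.append((la, lb, d))
            return merges

        for _ in range(20):
            n = int(rng.integers(3, 6))
            X = rng.random((n, 3))
            D = squareform(pdist(X))
            ids = [chr(65 + i) for i in range(n)]
            _, merges = upgma(DistanceMatrix(D, ids=ids))
            expected = reference(D, ids)
            for (a1, b1, d1), (a2, b2, d2) in zip(merges, expected):
                assert {a1, b1} == {a2, b2}
                assert d1 == pytest.approx(d2)

    def test_heights_match_scipy_average_linkage(self, rng):
        X = rng.random((7, 4))
        D = squareform(pdist(X))
        ids = [f"u{i}" for i in range(7)]
        _, merges = upgma(DistanceMatrix(D, ids=ids))
        Z = scipy_average(pdist(X))
        np.testing.assert_allclose(
            sorted(m[2] for m in merges), sorted(Z[:, 2]), rtol=1e-10
        )

    def test_cluster_cut(self):
        dm = DistanceMatrix(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        _, merges = upgma(dm)
        groups = clusters_at(merges, ["A", "B", "C"], 2)
        assert sorted(map(sorted, groups)) == [["A", "B"], ["C"]]

    def test_nan_rejected(self):
        D = np.zeros((2, 2))
        dm = DistanceMatrix(D, ids=["a", "b"])
        dm.data[0, 1] = dm.data[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            upgma(dm)


class TestInverseNormal:
    def test_three_entry_closed_form(self):
        dm = DistanceMatrix([[0, 0.2, 0.5], [0.2, 0, 0.9], [0.5, 0.9, 0]],
                            ids=list("abc"))
        out = inverse_normal_transform(dm)
        q = stats.norm.ppf([(1 - 0.375) / 3.25, (2 - 0.375) / 3.25, (3 - 0.375) / 3.25])
        expected = q - q.min()
        got = sorted([out["a", "b"], out["a", "c"], out["b", "c"]])
        np.testing.assert_allclose(got, sorted(expected), atol=1e-12)
        # median entry maps to the centre quantile (0 before the shift)
        assert out["a", "c"] == pytest.approx(0.0 - q.min())

    def test_monotone_and_nonnegative(self, rng):
        D = squareform(pdist(rng.random((6, 3))))
        dm = DistanceMatrix(D, ids=[str(i) for i in range(6)])
        out = inverse_normal_transform(dm)
        iu = np.triu_indices(6, k=1)
        orig, trans = D[iu], out.data[iu]
        order = np.argsort(orig)
        assert (np.diff(trans[order]) >= 0).all()
        assert (trans >= 0).all()
        assert np.diag(out.data).sum() == 0

    def test_too_few_entries_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 2"):
            inverse_normal_transform(dm)
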