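"""Alpha diversity closed forms, UniFrac against a brute-force oracle,
PCoA distance reconstruction, PERMANOVA behaviour."""

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform

from conftest import brute_force_unifrac
from igaseq import (CountTable, alpha_diversity, compare_alpha, pcoa,
                    permanova, read_tree, simulate_tree, unweighted_unifrac)


def _table(columns: dict, taxa=None) -> CountTable:
    taxa = taxa or [f"T{i}" for i in range(len(next(iter(columns.values()))))]
    return CountTable(pd.DataFrame(columns, index=pd.Index(taxa, name="taxon_id")))


class TestAlpha:
    def test_uniform_profile_closed_forms(self):
        table = _table({"s": [10, 10, 10, 10]})
        assert alpha_diversity(table, "observed")["s"] == 4
        assert alpha_diversity(table, "shannon")["s"] == pytest.approx(np.log(4))
        assert alpha_diversity(table, "invsimpson")["s"] == pytest.approx(4.0)

    def test_single_taxon_sample(self):
        table = _table({"s": [7, 0, 0]})
        assert alpha_diversity(table, "observed")["s"] == 1
        assert alpha_diversity(table, "shannon")["s"] == 0.0
        assert alpha_diversity(table, "invsimpson")["s"] == pytest.approx(1.0)

    def test_invsimpson_hand_value(self):
        table = _table({"s": [2, 1, 1]})  # proportions 0.5, 0.25, 0.25
        assert alpha_diversity(table, "invsimpson")["s"] == pytest.approx(8 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_diversity(_table({"s": [0, 0]}), "shannon")

    def test_shannon_maximized_by_uniform(self):
        rng = np.random.default_rng(0)
        uniform = np.log(6)
        for _ in range(50):
            counts = rng.integers(1, 60, 6)
            p = counts / counts.sum()
            assert -(p * np.log(p)).sum() <= uniform + 1e-12

    def test_compare_alpha_separated_groups(self, paired_manifest):
        alpha = pd.DataFrame(
            {"observed": [1, 2, 3, 4, 11, 12, 13, 14]},
            index=[f"{s}_{f}" for s in ("A00", "A01", "H00", "H01")
                   for f in ("pos", "neg")])
        out = compare_alpha(alpha, paired_manifest)
        # complete separation at 4 vs 4: exact two-sided p = 2/70
        assert out.loc[0, "p"] == pytest.approx(2 / 70)


class TestUniFrac:
    tree = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_identical_profiles_zero(self):
        table = _table({"s1": [1, 1, 0, 0], "s2": [3, 9, 0, 0]}, list("ABCD"))
        dm = unweighted_unifrac(table, read_tree(self.tree))
        assert dm["s1", "s2"] == 0.0

    def test_disjoint_star_tree_distance_one(self):
        star = read_tree("(A:1,B:1,C:1,D:1);")
        table = _table({"s1": [1, 1, 0, 0], "s2": [0, 0, 2, 5]}, list("ABCD"))
        dm = unweighted_unifrac(table, star, prune=False)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_worked_small_tree(self):
        # samples {A,B} vs {A,C}: unique branches B, C and the internal
        # branch above {C,D}; shared: A and the internal branch above
        # {A,B}; distance = 3/5
        table = _table({"s1": [1, 1, 0, 0], "s2": [1, 0, 1, 0]}, list("ABCD"))
        dm = unweighted_unifrac(table, read_tree(self.tree))
        oracle = brute_force_unifrac(read_tree(self.tree), {"A", "B"}, {"A", "C"})
        assert oracle == pytest.approx(3 / 5)
        assert dm["s1", "s2"] == pytest.approx(oracle)

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for rep in range(20):
            ids = [f"L{i}" for i in range(8)]
            tree = simulate_tree(ids, seed=rep)
            presence = rng.integers(0, 2, (8, 3))
            presence[0, presence.sum(axis=0) == 0] = 1  # no empty sample
            table = _table({f"s{j}": presence[:, j] for j in range(3)}, ids)
            dm = unweighted_unifrac(table, tree)
            for i in range(3):
                for j in range(i + 1, 3):
                    a = {ids[k] for k in range(8) if presence[k, i]}
                    b = {ids[k] for k in range(8) if presence[k, j]}
                    expected = brute_force_unifrac(tree, a, b)
                    assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-12)

    def test_metric_properties(self):
        rng = np.random.default_rng(9)
        ids = [f"L{i}" for i in range(8)]
        tree = simulate_tree(ids, seed=77)
        presence = rng.integers(0, 2, (8, 5))
        presence[:, presence.sum(axis=0) == 0] = 1
        table = _table({f"s{j}": presence[:, j] for j in range(5)}, ids)
        d = unweighted_unifrac(table, tree).data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_taxon_requires_prune(self):
        table = _table({"s1": [1, 1, 1], "s2": [0, 1, 1]}, ["A", "B", "X"])
        tree = read_tree(self.tree)
        with pytest.raises(ValueError, match="prune"):
            unweighted_unifrac(table, tree)
        dm = unweighted_unifrac(table, tree, prune=True)
        assert dm.shape == (2, 2)


class TestPCoA:
    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(1)
        for rep in range(5):
            pts = rng.normal(size=(7, 3))
            d = squareform(pdist(pts))
            coords = pcoa(skbio.DistanceMatrix(d)).coordinates.to_numpy()
            recon = squareform(pdist(coords))
            np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_known_triangle(self):
        d = squareform(pdist(np.array([[0, 0], [3, 0], [0, 4]])))
        res = pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(squareform(pdist(res.coordinates)), d,
                                   atol=1e-9)
        assert res.eigenvalues[0] >= res.eigenvalues[1] >= 0

    def test_all_zero_distances(self):
        res = pcoa(skbio.DistanceMatrix(np.zeros((4, 4))))
        np.testing.assert_allclose(res.eigenvalues, 0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as sk_pcoa
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(6, 4))))
        dm = skbio.DistanceMatrix(d)
        ours = pcoa(dm)
        theirs = sk_pcoa(dm)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9])[::-1],
            np.sort(np.asarray(theirs.eigvals)[np.asarray(theirs.eigvals) > 1e-9])[::-1],
            rtol=1e-8)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPermanova:
    def _dm(self, pts):
        return skbio.DistanceMatrix(squareform(pdist(pts)),
                                    ids=[str(i) for i in range(len(pts))])

    def test_separated_clusters_minimal_p(self):
        # 10 vs 10 so no random permutation reproduces the grouping:
        # p attains its minimum 1/(n_perm + 1)
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)),
                         rng.normal(10, 0.05, (10, 2))])
        res = permanova(self._dm(pts), ["a"] * 10 + ["b"] * 10, n_perm=199,
                        seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert 0 < res.R2 < 1

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        labels = ["a"] * 6 + ["b"] * 6
        dm = self._dm(pts)
        f1 = permanova(dm, labels, n_perm=99, seed=2).pseudo_F
        perm = rng.permutation(12)
        dm2 = skbio.DistanceMatrix(dm.data[np.ix_(perm, perm)],
                                   ids=[str(i) for i in range(12)])
        f2 = permanova(dm2, [labels[i] for i in perm], n_perm=99, seed=2).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(14, 3))
        pts[:7] += 1.0
        dm = self._dm(pts)
        labels = ["a"] * 7 + ["b"] * 7
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = sk_permanova(dm, labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        dm = self._dm(rng.normal(size=(10, 2)))
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova(dm, labels, n_perm=199, seed=7)
        r2 = permanova(dm, labels, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value

    def test_degenerate_rejected(self):
        dm = skbio.DistanceMatrix(np.zeros((6, 6)))
        with pytest.raises(ValueError, match="degenerate"):
            permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
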