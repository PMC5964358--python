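"""Beta diversity distances, ordination, MANOVA, PERMANOVA, paired shifts."""

import numpy as np
import pandas as pd
import pytest

import guildscan as gs
from oracles import anova_f, mannwhitney_exact_p
from test_otus import mk_table


def star_tree(otu_ids):
    return "(" + ",".join(f"{o}:1.0" for o in otu_ids) + ");"


class TestDistances:
    def test_identical_samples_zero_everywhere(self):
        table = mk_table([[3, 1, 2], [3, 1, 2]])
        tree = star_tree(table.otu_ids)
        for metric in gs.beta.BETA_METRICS:
            dm = gs.distance_matrix(table, metric, tree=tree)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12), metric

    def test_disjoint_samples_distance_one(self):
        table = mk_table([[5, 3, 0, 0], [0, 0, 2, 6]])
        tree = star_tree(table.otu_ids)
        for metric in ("bray_curtis", "jaccard_binary", "jaccard_weighted", "unifrac_unweighted"):
            dm = gs.distance_matrix(table, metric, tree=tree)
            assert dm.data[0, 1] == pytest.approx(1.0), metric

    def test_bray_curtis_hand_value(self):
        # counts (2,0,1) vs (1,1,1): BC on relative abundances = sum|x-y|/sum(x+y)
        table = mk_table([[2, 0, 1], [1, 1, 1]])
        dm = gs.distance_matrix(table, "bray_curtis")
        x = np.array([2, 0, 1]) / 3
        y = np.array([1, 1, 1]) / 3
        assert dm.data[0, 1] == pytest.approx(np.abs(x - y).sum() / (x + y).sum())
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_cross_check_scipy_braycurtis(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(0)
        table = mk_table(rng.integers(1, 50, size=(4, 8)))
        rel = gs.relative_abundance(table).to_numpy()
        dm = gs.distance_matrix(table, "bray_curtis")
        for i in range(4):
            for j in range(4):
                assert dm.data[i, j] == pytest.approx(braycurtis(rel[i], rel[j]), abs=1e-12)

    def test_presence_absence_weighted_equals_binary_jaccard(self):
        # equal-richness presence/absence rows: closure scales all samples
        # identically, so min/max reduces to intersection/union
        table = mk_table([[1, 1, 0, 1], [0, 1, 1, 1], [1, 0, 1, 1]])
        jw = gs.distance_matrix(table, "jaccard_weighted")
        jb = gs.distance_matrix(table, "jaccard_binary")
        assert np.allclose(jw.data, jb.data)

    def test_all_metrics_bounded(self):
        rng = np.random.default_rng(1)
        table = mk_table(rng.integers(0, 40, size=(6, 10)) + (rng.random((6, 10)) < 0.5))
        tree = star_tree(table.otu_ids)
        for metric in gs.beta.BETA_METRICS:
            dm = gs.distance_matrix(table, metric, tree=tree)
            assert dm.data.min() >= 0 and dm.data.max() <= 1 + 1e-12, metric

    def test_unifrac_star_tree_closed_form(self):
        # on a star tree with unit branches, unweighted UniFrac reduces to
        # (unique branches)/(observed branches) = binary Jaccard
        rng = np.random.default_rng(2)
        table = mk_table((rng.random((5, 8)) < 0.6).astype(int) * rng.integers(1, 9, (5, 8)))
        tree = star_tree(table.otu_ids)
        uu = gs.distance_matrix(table, "unifrac_unweighted", tree=tree)
        jb = gs.distance_matrix(table, "jaccard_binary")
        assert np.allclose(uu.data, jb.data, atol=1e-12)

    def test_missing_tree_leaves_reported(self):
        table = mk_table([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="OTU2"):
            gs.distance_matrix(table, "unifrac_unweighted", tree="(OTU1:1.0,X:1.0);")


class TestPca:
    def test_explained_variance_sums_to_total(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        res = gs.pca(X)
        total = X.to_numpy().var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total)

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=5)
        X = pd.DataFrame(np.vstack([row, row, rng.normal(size=5)]))
        res = gs.pca(X)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_two_samples_single_component(self):
        X = pd.DataFrame([[0.0, 1.0, 2.0], [1.0, 3.0, 2.0]])
        res = gs.pca(X)
        assert np.sum(res.eigenvalues > 1e-12) == 1


class TestPcoa:
    def test_planar_points_roundtrip(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = gs.DistanceMatrix([f"s{i}" for i in range(10)], d)
        res = gs.pcoa(dm)
        coords = res.scores.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = gs.DistanceMatrix([f"s{i}" for i in range(8)], d)
        res = gs.pcoa(dm)
        D2 = d**2
        J = np.eye(8) - np.ones((8, 8)) / 8
        B = -0.5 * J @ D2 @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B))

    def test_three_equidistant_points_degenerate_pair(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = gs.pcoa(gs.DistanceMatrix(list("abc"), d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_cross_check_against_skbio(self):
        import skbio
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(9)]
        ours = gs.pcoa(gs.DistanceMatrix(ids, d))
        theirs = skbio_pcoa(skbio.DistanceMatrix(d, ids=ids), method="eigh")
        k = min(4, ours.scores.shape[1])
        assert np.allclose(
            np.sort(ours.eigenvalues[:k]), np.sort(theirs.eigvals.to_numpy()[:k]), atol=1e-8
        )


class TestManova:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=(50, 2))
        b = rng.normal(2, 1, size=(50, 2))
        scores = pd.DataFrame(np.vstack([a, b]), columns=["PC1", "PC2"])
        labels = ["A"] * 50 + ["B"] * 50
        f, p = gs.beta.manova_on_scores(scores, labels)
        assert p < 1e-4

    def test_single_group_error(self):
        scores = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="two groups"):
            gs.beta.manova_on_scores(scores, ["A"] * 10)


class TestPermanova:
    def test_separated_clouds_minimum_p(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = gs.DistanceMatrix([f"s{i}" for i in range(20)], d)
        f, p = gs.permanova(dm, ["A"] * 10 + ["B"] * 10, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_1d_equals_anova_f(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        labels = np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        d = np.abs(x[:, None] - x[None, :])
        dm = gs.DistanceMatrix([f"s{i}" for i in range(15)], d)
        f, _ = gs.permanova(dm, labels, n_perm=19, seed=0)
        assert f == pytest.approx(anova_f(x, labels))

    def test_cross_check_against_skbio(self):
        import skbio
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(10)
        pts = rng.normal(size=(18, 3))
        pts[9:] += 0.8
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(18)]
        labels = ["A"] * 9 + ["B"] * 9
        f_ours, _ = gs.permanova(gs.DistanceMatrix(ids, d), labels, n_perm=19, seed=0)
        res = skbio_permanova(skbio.DistanceMatrix(d, ids=ids), grouping=labels, permutations=19)
        assert f_ours == pytest.approx(res["test statistic"])

    def test_among_within_ratio_invariant_under_balanced_duplication(self):
        # the scale-free SS_among/SS_within ratio is duplication-invariant
        # (the F itself changes through its degrees of freedom)
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 2))
        pts[4:] += 1.0
        labels = np.array(["A"] * 4 + ["B"] * 4)
        d1 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        pts2 = np.vstack([pts, pts])
        labels2 = np.concatenate([labels, labels])
        d2 = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=2)
        from guildscan.beta import _permanova_ss

        t1, w1, _ = _permanova_ss(d1**2, labels)
        t2, w2, _ = _permanova_ss(d2**2, labels2)
        assert (t1 - w1) / w1 == pytest.approx((t2 - w2) / w2)

    def test_group_of_one_rejected(self):
        d = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        dm = gs.DistanceMatrix(list("abcd"), d)
        with pytest.raises(ValueError, match="at least two members"):
            gs.permanova(dm, ["A", "A", "A", "B"], n_perm=9, seed=0)


class TestMannWhitneyOracle:
    def test_exact_p_matches_enumeration(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        for n, m in ((4, 4), (5, 8), (8, 8)):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.8, 1, m)
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p_scipy == pytest.approx(mannwhitney_exact_p(x, y))


class TestPairedShift:
    def test_zero_shift_for_identical_timepoints(self):
        counts = np.array([[5, 3, 2], [5, 3, 2], [1, 8, 1], [1, 8, 1]])
        meta = pd.DataFrame(
            {
                "subject": ["p1", "p1", "p2", "p2"],
                "arm": ["A", "A", "B", "B"],
                "timepoint": ["week0", "week12", "week0", "week12"],
            },
            index=["p1_w0", "p1_w12", "p2_w0", "p2_w12"],
        )
        table = mk_table(counts, samples=list(meta.index), meta=meta)
        dm = gs.distance_matrix(table, "bray_curtis")
        assert dm.between("p1_w0", "p1_w12") == 0.0

    def test_planted_arm_shift_detected(self, planted_cohort):
        spec, effect, ds = planted_cohort
        # rebuild with the effect confined to arm A for a between-arm contrast
        effect_a = gs.EffectSpec(
            target_guilds=[4], log2_fold_change=[2.0], arm="A"
        )
        ds_a = gs.generate_paired_cohort(50, spec, effect_a, seed=21)
        combined = ds_a.combined_table()
        dm = gs.distance_matrix(combined, "bray_curtis")
        out = gs.beta.paired_shift_comparison({"bray_curtis": dm}, combined.sample_meta)
        row = out.loc["bray_curtis"]
        assert row["median_shift_A"] > row["median_shift_B"]
        assert row["p"] < 0.05
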