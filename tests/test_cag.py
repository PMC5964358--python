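"""Co-abundance groups: correlation distance, Ward, PERMANOVA partition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import guildscan as gs


def block_rho(n_blocks, size, within, between=0.0):
    d = n_blocks * size
    rho = np.full((d, d), between)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        rho[sl, sl] = within
    np.fill_diagonal(rho, 1.0)
    ids = [f"OTU{i + 1}" for i in range(d)]
    return pd.DataFrame(rho, index=ids, columns=ids)


class TestCorrelationDistance:
    @pytest.mark.parametrize("rho,expected", [(1.0, 0.0), (-1.0, 2.0), (0.4, 0.6)])
    def test_linear_transform(self, rho, expected):
        mat = block_rho(1, 2, rho)
        dm = gs.correlation_distance(mat)
        assert dm.data[0, 1] == pytest.approx(expected)

    def test_asymmetric_rejected(self):
        mat = block_rho(1, 3, 0.5)
        mat.iloc[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            gs.correlation_distance(mat)


class TestWardTree:
    def test_two_tight_blocks_top_split(self):
        rng = np.random.default_rng(0)
        rho = block_rho(2, 5, 0.9).to_numpy() + rng.normal(0, 0.01, (10, 10))
        rho = np.clip((rho + rho.T) / 2, -1, 1)
        np.fill_diagonal(rho, 1.0)
        ids = [f"OTU{i + 1}" for i in range(10)]
        dm = gs.correlation_distance(pd.DataFrame(rho, index=ids, columns=ids))
        Z = gs.ward_tree(dm)
        from scipy.cluster.hierarchy import fcluster

        cut = fcluster(Z, t=2, criterion="maxclust")
        order = sorted(ids)
        truth = [0 if int(o[3:]) <= 5 else 1 for o in order]
        assert adjusted_rand_score(truth, cut) == 1.0

    def test_heights_monotone(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = gs.DistanceMatrix([f"OTU{i}" for i in range(12)], d)
        Z = gs.ward_tree(dm)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_single_pair_one_merge(self):
        dm = gs.correlation_distance(block_rho(1, 2, 0.3))
        Z = gs.ward_tree(dm)
        assert Z.shape[0] == 1


class TestPartition:
    def test_planted_guilds_recovered(self, planted_guilds):
        spec, data, result = planted_guilds
        dm = gs.correlation_distance(result.rho_frame())
        part = gs.partition_by_permanova(gs.ward_tree(dm), dm, alpha=0.001, n_perm=999, seed=5)
        assert part.n_cags == 4
        truth = [data.guild_of[o] for o in part.otu_ids]
        pred = [part.assignment[o] for o in part.otu_ids]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_no_structure_stays_whole(self):
        spec = gs.GuildSpec(4, 10, within_corr=0.3, between_corr=0.3)
        data = gs.generate_guild_counts(100, spec, seed=50)
        res = gs.sparcc(data.table.counts, n_draws=5, n_bootstrap=0, seed=51)
        dm = gs.correlation_distance(res.rho_frame())
        part = gs.partition_by_permanova(gs.ward_tree(dm), dm, alpha=0.001, n_perm=99, seed=52)
        assert part.n_cags == 1

    def test_alpha_one_splits_until_singleton_rule(self, planted_guilds):
        spec, data, result = planted_guilds
        dm = gs.correlation_distance(result.rho_frame())
        part = gs.partition_by_permanova(gs.ward_tree(dm), dm, alpha=1.0, n_perm=9, seed=0)
        assert all(accepted for _, _, accepted in part.split_pvalues)
        assert part.n_cags > 4

    def test_order_invariance(self, planted_guilds):
        spec, data, result = planted_guilds
        rho = result.rho_frame()
        perm = np.random.default_rng(3).permutation(len(rho))
        rho_shuffled = rho.iloc[perm, perm]
        dm1 = gs.correlation_distance(rho)
        dm2 = gs.correlation_distance(rho_shuffled)
        p1 = gs.partition_by_permanova(gs.ward_tree(dm1), dm1, n_perm=99, seed=7)
        p2 = gs.partition_by_permanova(gs.ward_tree(dm2), dm2, n_perm=99, seed=7)
        m1, m2 = p1.members(), p2.members()
        assert sorted(map(tuple, m1.values())) == sorted(map(tuple, m2.values()))


class TestCagAbundance:
    def mk_partition(self, assignment):
        return gs.cag.CagPartition(assignment, np.empty((0, 4)), sorted(assignment), [], 0.001)

    def test_sum_conservation(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=5), columns=[f"OTU{i + 1}" for i in range(6)]
        )
        part = self.mk_partition(
            {"OTU1": "CAG1", "OTU2": "CAG1", "OTU3": "CAG2", "OTU4": "CAG2", "OTU5": "CAG2", "OTU6": "CAG3"}
        )
        table = gs.cag_abundance(rel, part)
        assert np.allclose(table.abundance.sum(axis=1), rel.sum(axis=1), atol=1e-12)
        assert table.abundance.loc[0, "CAG1"] == pytest.approx(rel.loc[0, ["OTU1", "OTU2"]].sum())

    def test_single_cag_equals_total(self):
        rel = pd.DataFrame([[0.1, 0.2, 0.3]], columns=["OTU1", "OTU2", "OTU3"])
        part = self.mk_partition({o: "CAG1" for o in rel.columns})
        table = gs.cag_abundance(rel, part)
        assert table.abundance.iloc[0, 0] == pytest.approx(0.6)

    def test_missing_otu_errors(self):
        rel = pd.DataFrame([[1.0]], columns=["OTU1"])
        part = self.mk_partition({"OTU1": "CAG1", "OTU9": "CAG1"})
        with pytest.raises(KeyError, match="OTU9"):
            gs.cag_abundance(rel, part)


class TestComparePaired:
    def test_planted_effect_one_arm_only(self):
        spec = gs.GuildSpec(4, 5, 0.8)
        effect = gs.EffectSpec(target_guilds=[1], log2_fold_change=[1.0], arm="A")
        ds = gs.generate_paired_cohort(50, spec, effect, seed=31)
        combined = ds.combined_table()
        rel = gs.relative_abundance(combined)
        assignment = {o: f"CAG{g + 1}" for o, g in ds.truth["guild_of"].items()}
        part = gs.cag.CagPartition(assignment, np.empty((0, 4)), sorted(assignment), [], 0.001)
        table = gs.cag_abundance(rel, part)
        res_a = gs.compare_cag_paired(table, combined.sample_meta, arm="A")
        res_b = gs.compare_cag_paired(table, combined.sample_meta, arm="B")
        assert res_a.loc["CAG2", "p"] < 0.05 and res_a.loc["CAG2", "median_delta"] > 0
        assert res_b.loc["CAG2", "p"] > 0.05

    def test_identical_timepoints_error(self):
        ab = pd.DataFrame(
            {"CAG1": [0.5, 0.5, 0.4, 0.4]}, index=["p1_w0", "p1_w12", "p2_w0", "p2_w12"]
        )
        meta = pd.DataFrame(
            {
                "subject": ["p1", "p1", "p2", "p2"],
                "arm": ["A"] * 4,
                "timepoint": ["week0", "week12"] * 2,
            },
            index=ab.index,
        )
        table = gs.cag.CagAbundanceTable(ab, {"CAG1": ["OTU1"]})
        with pytest.raises(ValueError, match="nonzero"):
            gs.compare_cag_paired(table, meta, arm="A")


class TestNetworkExport:
    def mk(self, rho):
        assignment = {o: ("CAG1" if int(o[3:]) <= len(rho) // 2 else "CAG2") for o in rho.index}
        part = gs.cag.CagPartition(assignment, np.empty((0, 4)), sorted(assignment), [], 0.001)
        mean_ab = {o: 0.1 for o in rho.index}
        return part, mean_ab

    def test_all_below_threshold_empty(self, tmp_path):
        rho = block_rho(2, 3, 0.2)
        part, mean_ab = self.mk(rho)
        g, nodes, edges = gs.export_network(rho, part, mean_ab, edge_threshold=0.4)
        assert len(edges) == 0
        assert nodes["excluded_from_display"].all()

    def test_threshold_minus_one_complete(self):
        rho = block_rho(2, 3, 0.2, between=0.1)
        part, mean_ab = self.mk(rho)
        g, nodes, edges = gs.export_network(rho, part, mean_ab, edge_threshold=-1.0)
        assert len(edges) == 6 * 5 // 2

    def test_two_block_structure_edges_within_blocks(self, tmp_path):
        rho = block_rho(2, 4, 0.8, between=0.0)
        part, mean_ab = self.mk(rho)
        g, nodes, edges = gs.export_network(
            rho, part, mean_ab, edge_threshold=0.4,
            edge_path=tmp_path / "e.tsv", node_path=tmp_path / "n.tsv",
            graphml_path=tmp_path / "g.graphml",
        )
        for _, row in edges.iterrows():
            assert part.assignment[row["source"]] == part.assignment[row["target"]]
        assert (tmp_path / "g.graphml").exists()
        back = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(back) == len(edges) == 2 * (4 * 3 // 2)
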