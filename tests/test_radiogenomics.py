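"""Expression filtering, feature-gene correlation under FDR, clustering and
enrichment-list export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

import prorad as pr
from prorad.radiogenomics import linkage_to_newick


def _random_pair(n_samples=17, n_features=8, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    feats = pd.DataFrame(rng.normal(size=(n_samples, n_features)),
                         index=samples,
                         columns=[f"F{i}" for i in range(n_features)])
    expr = pd.DataFrame(rng.normal(0.5, 0.15, size=(n_genes, n_samples)),
                        index=[f"G{i:03d}" for i in range(n_genes)],
                        columns=samples)
    return feats, expr


class TestFilter:
    def test_low_median_low_iqr_removed(self):
        expr = pd.DataFrame([np.full(6, 0.1) + np.linspace(0, 0.2, 6)],
                            index=["g"], columns=list("abcdef"))
        # median 0.2 < 0.25, IQR 0.1 < 0.5 -> removed
        out, log = pr.filter_expression(expr)
        assert log.loc["g", "removed"] and out.empty

    def test_low_median_high_iqr_retained(self):
        vals = np.array([0.0, 0.0, 0.1, 0.1, 1.0, 1.2])  # median 0.1, IQR 0.9
        expr = pd.DataFrame([vals], index=["g"], columns=list("abcdef"))
        out, log = pr.filter_expression(expr)
        assert not log.loc["g", "removed"]
        assert "g" in out.index

    def test_or_mode_removes_on_either_condition(self):
        vals = np.array([0.0, 0.0, 0.1, 0.1, 1.0, 1.2])
        expr = pd.DataFrame([vals], index=["g"], columns=list("abcdef"))
        out, log = pr.filter_expression(expr, mode="or")
        assert log.loc["g", "removed"]

    def test_empty_result_warns(self):
        expr = pd.DataFrame([[0.1, 0.1, 0.1]], index=["g"], columns=list("abc"))
        with pytest.warns(UserWarning):
            out, _ = pr.filter_expression(expr)
        assert out.empty


class TestCorrelate:
    def test_matches_pearsonr_oracle_elementwise(self):
        feats, expr = _random_pair(seed=5)
        res = pr.correlate(feats, expr)
        for f in feats.columns[:3]:
            for g in expr.index[:5]:
                r_ref, p_ref = stats.pearsonr(feats[f], expr.loc[g])
                assert res.r.at[f, g] == pytest.approx(r_ref, abs=1e-12)
                assert res.p.at[f, g] == pytest.approx(p_ref, rel=1e-9)

    def test_planted_duplicate_is_fdr_significant(self):
        feats, expr = _random_pair(seed=6)
        expr.loc["G000"] = feats["F0"].to_numpy()
        res = pr.correlate(feats, expr)
        assert res.r.at["F0", "G000"] == pytest.approx(1.0)
        assert res.p_fdr.at["F0", "G000"] < 0.05

    def test_bh_stepup_matches_oracle(self):
        # the spec's toy sequence: all adjusted values collapse to max(i/m * p)
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = len(p)
        order = np.argsort(p)[::-1]
        adj = np.empty(m)
        running = 1.0
        for idx in order:  # hand step-up from largest p
            rank = np.searchsorted(np.sort(p), p[idx]) + 1
            running = min(running, m * p[idx] / rank)
            adj[idx] = running
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        from statsmodels.stats.multitest import multipletests
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh, adj, rtol=1e-12)

    def test_bh_monotone_and_counts(self):
        feats, expr = _random_pair(seed=7)
        res = pr.correlate(feats, expr)
        p = res.p.to_numpy().ravel()
        q = res.p_fdr.to_numpy().ravel()
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert res.n_significant_fdr <= res.significant_raw.to_numpy().sum()
        assert np.all(q >= p - 1e-12)

    def test_transpose_symmetry(self):
        feats, expr = _random_pair(seed=8)
        res = pr.correlate(feats, expr)
        swapped = pr.correlate(expr.T, feats.T)
        np.testing.assert_allclose(res.r.to_numpy(), swapped.r.to_numpy().T,
                                   atol=1e-12)

    def test_constant_feature_excluded_with_warning(self):
        feats, expr = _random_pair(seed=9)
        feats["F0"] = 1.0
        with pytest.warns(UserWarning, match="F0"):
            res = pr.correlate(feats, expr)
        assert "F0" in res.dropped_features
        assert "F0" not in res.r.index

    def test_too_few_shared_samples_rejected(self):
        feats, expr = _random_pair(n_samples=3)
        with pytest.raises(pr.ConfigurationError):
            pr.correlate(feats, expr)

    def test_null_calibration_raw_rate(self):
        # independent data: raw p < 0.05 in ~5% of pairs; FDR count ~ 0
        rates, fdr_counts = [], []
        for seed in range(60):
            feats, expr = _random_pair(n_samples=17, n_features=10,
                                       n_genes=60, seed=100 + seed)
            res = pr.correlate(feats, expr)
            rates.append(res.significant_raw.to_numpy().mean())
            fdr_counts.append(res.n_significant_fdr)
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)
        assert np.mean(fdr_counts) < 0.5


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        rng = np.random.default_rng(11)
        M = pd.DataFrame(rng.normal(size=(5, 8)))
        M.iloc[3] = M.iloc[1]
        res = pr.cluster_heatmap(M)
        Z = res["row_linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {1, 3}

    def test_average_linkage_matches_hand_agglomeration(self):
        # 4 profiles engineered so correlation distances are easy to verify
        rng = np.random.default_rng(13)
        M = pd.DataFrame(rng.normal(size=(4, 10)))
        r = np.corrcoef(M.to_numpy())
        d = 1 - r
        # hand-run average-linkage on the 4x4 distance matrix
        from scipy.spatial.distance import squareform
        Z_ref = hierarchy.linkage(squareform(d, checks=False), method="average")
        Z = pr.cluster_heatmap(M)["row_linkage"]
        np.testing.assert_allclose(Z, Z_ref)
        # independent check of the first merge: the closest pair
        iu = np.triu_indices(4, 1)
        assert Z[0, 2] == pytest.approx(d[iu].min())

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(14)
        M = pd.DataFrame(rng.normal(size=(7, 9)))
        res = pr.cluster_heatmap(M)
        assert sorted(res["row_order"]) == list(range(7))
        assert sorted(res["col_order"]) == list(range(9))

    def test_heatmap_file_written(self, tmp_path):
        rng = np.random.default_rng(15)
        M = pd.DataFrame(rng.uniform(-1, 1, size=(5, 6)),
                         columns=[f"G{i}" for i in range(6)])
        sigs = {"CCP": {"up": ["G0"], "down": ["G1"]}}
        out = tmp_path / "heat.png"
        pr.cluster_heatmap(M, out_path=out, signatures=sigs)
        assert out.stat().st_size > 0


class TestSampleClustering:
    def test_identical_profiles_zero_height_merge(self):
        feats, expr = _random_pair(seed=16)
        expr["S01"] = expr["S00"]
        res = pr.sample_clustering(expr)
        Z = res["linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_groups_recovered(self):
        rng = np.random.default_rng(17)
        n_genes = 40
        base_a = rng.normal(size=n_genes)
        base_b = -base_a
        cols = {}
        for i in range(6):
            cols[f"A{i}"] = base_a + 0.05 * rng.normal(size=n_genes)
        for i in range(6):
            cols[f"B{i}"] = base_b + 0.05 * rng.normal(size=n_genes)
        expr = pd.DataFrame(cols)
        res = pr.sample_clustering(expr)
        groups = hierarchy.fcluster(res["linkage"], t=2, criterion="maxclust")
        by_label = {}
        for lab, g in zip(res["labels"], groups):
            by_label.setdefault(g, set()).add(lab[0])
        assert sorted(map(tuple, map(sorted, by_label.values()))) == [("A",), ("B",)]

    def test_newick_roundtrip_preserves_topology(self):
        feats, expr = _random_pair(seed=18, n_samples=6)
        res = pr.sample_clustering(expr)
        import skbio
        tree = skbio.TreeNode.read([res["newick"]])
        assert {t.name for t in tree.tips()} == set(res["labels"])
        # sister pair of the first zero-height merge-free linkage: compare
        # the closest pair under the tree metric to the linkage's first merge
        first = {res["labels"][int(res["linkage"][0, 0])],
                 res["labels"][int(res["linkage"][0, 1])]}
        a, b = sorted(first)
        lca = tree.lowest_common_ancestor([a, b])
        assert {t.name for t in lca.tips()} == first

    def test_empty_subset_rejected(self):
        _, expr = _random_pair(seed=19)
        with pytest.raises(pr.ConfigurationError):
            pr.sample_clustering(expr, gene_subset=["NOPE"])


class TestEnrichmentExport:
    def test_lists_match_threshold_oracle(self, tmp_path):
        feats, expr = _random_pair(seed=20)
        expr.loc["G000"] = feats["F0"].to_numpy()  # guaranteed significant
        res = pr.correlate(feats, expr)
        lists = pr.export_enrichment_inputs(res, tmp_path)
        for f in res.p.index:
            expected = [g for g in res.p.columns if res.p.at[f, g] < 0.05]
            assert lists[f] == expected
            on_disk = (tmp_path / f"{f}.txt").read_text().split()
            assert on_disk == expected
        assert "G000" in lists["F0"]

    def test_feature_without_hits_writes_empty_file(self, tmp_path):
        feats, expr = _random_pair(seed=21, n_genes=3)
        res = pr.correlate(feats, expr)
        # force one feature to have no sub-threshold genes by raising cutoff
        lists = pr.export_enrichment_inputs(res, tmp_path, p_cutoff=1e-12)
        empty = [f for f, genes in lists.items() if not genes]
        assert empty
        assert (tmp_path / f"{empty[0]}.txt").read_text() == ""
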