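import numpy as np
import pytest
from scipy.stats import ks_2samp

import lungatlas as la

from conftest import ks_statistic_oracle, make_count_matrix


def nm_from_cpm(cpm):
    """NormalizedMatrix with prescribed CPM values (counts irrelevant)."""
    cpm = np.asarray(cpm, float)
    m = make_count_matrix(np.rint(cpm).astype(int))
    return la.NormalizedMatrix(cpm=cpm, source=m)


class TestKsStatistic:
    def test_perfectly_separating_gene_statistic_is_one(self):
        # positive in every cluster cell, zero in every other cell
        cpm = np.zeros((10, 2))
        cpm[:4, 0] = [5.0, 8.0, 3.0, 9.0]
        cpm[:, 1] = 1.0
        labels = np.array([1] * 4 + [0] * 6)
        res = la.ks_one_vs_rest(nm_from_cpm(cpm), labels, 1)
        assert res.loc[res["gene"] == "g0", "ks_statistic"].item() == 1.0

    def test_identical_distributions_statistic_zero(self):
        cpm = np.tile([[2.0, 3.0]], (8, 1))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = la.ks_one_vs_rest(nm_from_cpm(cpm), labels, 0)
        assert (res["ks_statistic"] == 0.0).all()

    def test_toy_groups(self):
        a, b = [1, 2, 3], [4, 5, 6]
        assert ks_statistic_oracle(a, b) == 1.0
        interleaved = ks_statistic_oracle([1, 3, 5], [2, 4, 6])
        assert np.isclose(
            ks_2samp([1, 3, 5], [2, 4, 6]).statistic, interleaved
        )

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1 = rng.integers(3, 50)
            n2 = rng.integers(3, 50)
            # mixed continuous and tied values
            a = np.round(rng.normal(size=n1), rng.integers(0, 2))
            b = np.round(rng.normal(0.3, size=n2), rng.integers(0, 2))
            assert abs(
                ks_2samp(a, b).statistic - ks_statistic_oracle(a, b)
            ) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        cpm = rng.gamma(2.0, 50.0, size=(30, 5))
        labels = np.array([0] * 15 + [1] * 15)
        nm = nm_from_cpm(cpm)
        s_lin = la.ks_one_vs_rest(nm, labels, 0)["ks_statistic"]
        nm_log = la.NormalizedMatrix(cpm=np.log10(cpm + 0.1), source=nm.source)
        s_log = la.ks_one_vs_rest(nm_log, labels, 0)["ks_statistic"]
        assert np.allclose(s_lin, s_log)

    def test_statistic_one_iff_disjoint_supports(self):
        rng = np.random.default_rng(2)
        # disjoint supports -> statistic 1
        a = rng.uniform(0, 1, size=20)
        b = rng.uniform(2, 3, size=25)
        assert ks_2samp(a, b).statistic == 1.0
        # overlapping supports -> statistic < 1
        c = rng.uniform(0, 2, size=20)
        d = rng.uniform(1, 3, size=25)
        assert ks_2samp(c, d).statistic < 1.0

    def test_degenerate_group_size_is_error(self):
        cpm = np.ones((3, 2))
        with pytest.raises(ValueError):
            la.ks_one_vs_rest(nm_from_cpm(cpm), np.array([0, 1, 1]), 0)


class TestLogFoldChange:
    def test_equal_means_give_zero(self):
        cpm = np.tile([[10.0, 20.0]], (6, 1))
        labels = np.array([0, 0, 0, 1, 1, 1])
        lfc = la.log2_fold_change(nm_from_cpm(cpm), labels, 0)
        assert np.allclose(lfc["log2_fold_change"], 0.0)

    def test_pseudocount_arithmetic(self):
        cpm = np.zeros((10, 1))
        cpm[:5, 0] = 819.1
        labels = np.array([0] * 5 + [1] * 5)
        lfc = la.log2_fold_change(nm_from_cpm(cpm), labels, 0, eps=0.1)
        assert np.isclose(
            lfc["log2_fold_change"].item(), np.log2(819.2 / 0.1), atol=1e-9
        )

    def test_swapping_groups_negates(self):
        rng = np.random.default_rng(3)
        cpm = rng.gamma(2.0, 30.0, size=(12, 4))
        labels = np.array([0] * 6 + [1] * 6)
        nm = nm_from_cpm(cpm)
        a = la.log2_fold_change(nm, labels, 0)["log2_fold_change"]
        b = la.log2_fold_change(nm, labels, 1)["log2_fold_change"]
        assert np.allclose(a, -b)


class TestDegTable:
    def test_planted_markers_dominate_top_of_table(
        self, pipeline_result, default_atlas, truth_labels
    ):
        _, truth = default_atlas
        labels = pipeline_result.labels
        ann = pipeline_result.annotations
        # pick the cluster annotated as B cells
        b_cluster = [cl for cl, n in ann.items() if n == "B"][0]
        table = la.deg_table(pipeline_result.normalized, labels, b_cluster, top_n=20)
        planted = {g for g, p in truth.marker_of.items() if p == "B"}
        frac = np.mean([g in planted for g in table["gene"]])
        assert frac >= 0.8

    def test_top_n_rows(self, pipeline_result):
        table = la.deg_table(pipeline_result.normalized, pipeline_result.labels, 0,
                             top_n=35)
        assert len(table) == 35
        assert (table["log2_fold_change"] > 0).all()
        assert (table["ks_statistic"].diff().dropna() <= 1e-12).all()

    def test_identical_clusters_give_zero_statistics(self):
        cpm = np.tile(np.arange(1.0, 7.0)[:, None], (2, 3))  # duplicated cells
        labels = np.array([0] * 6 + [1] * 6)
        res = la.ks_one_vs_rest(nm_from_cpm(cpm), labels, 0, versus=1)
        assert (res["ks_statistic"] == 0.0).all()

    def test_unknown_cluster_is_error(self):
        cpm = np.ones((6, 2))
        with pytest.raises(KeyError):
            la.deg_table(nm_from_cpm(cpm), np.array([0] * 3 + [1] * 3), 99, top_n=5)

    def test_exact_pvalue_for_small_clusters(self):
        # 8-cell cluster with a perfect marker: exact method gives the
        # tiny p-value that an asymptotic formula would overstate
        cpm = np.zeros((108, 1))
        cpm[:8, 0] = 10.0
        labels = np.array([1] * 8 + [0] * 100)
        res = la.ks_one_vs_rest(nm_from_cpm(cpm), labels, 1)
        assert res["ks_statistic"].item() == 1.0
        assert res["p_value"].item() < 1e-10
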