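import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import lungatlas as la
from lungatlas.normalize import PCAProjection

from conftest import make_count_matrix


def proj(coords):
    coords = np.asarray(coords, float)
    return PCAProjection(
        coordinates=coords,
        component_loadings=np.eye(coords.shape[1]),
        explained_variance=np.ones(coords.shape[1]),
        genes=[f"g{j}" for j in range(coords.shape[1])],
    )


class TestKnnGraph:
    def test_degree_at_least_k_after_union(self):
        rng = np.random.default_rng(0)
        g = la.build_knn_graph(proj(rng.normal(size=(40, 3))), k=5)
        deg = np.asarray(g.sum(axis=1)).ravel()
        assert (deg >= 5).all()

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        g = la.build_knn_graph(proj(rng.normal(size=(30, 2))), k=4)
        assert (g != g.T).nnz == 0

    def test_equidistant_ties_broken_by_ascending_index(self):
        # unit square, k=1: each node ties between its two side-neighbors
        # (distance exactly 1) and must pick the lower-index one
        pts = [[0, 0], [1, 0], [0, 1], [1, 1]]
        g1 = la.build_knn_graph(proj(pts), k=1)
        g2 = la.build_knn_graph(proj(pts), k=1)
        assert (g1 != g2).nnz == 0
        # directed picks 0->1, 1->0, 2->0, 3->1; union = {0-1, 0-2, 1-3}
        edges = {tuple(sorted(e)) for e in zip(*g1.nonzero())}
        assert edges == {(0, 1), (0, 2), (1, 3)}

    def test_separated_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(25, 2))
        b = rng.normal(size=(25, 2)) + 1000.0
        g = la.build_knn_graph(proj(np.vstack([a, b])), k=5)
        cross = g[:25, 25:]
        assert cross.nnz == 0

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError):
            la.build_knn_graph(proj(np.zeros((5, 2))), k=5)


class TestLeiden:
    def test_two_disconnected_cliques(self):
        n = 10
        block = np.ones((n, n)) - np.eye(n)
        adj = sp.block_diag([block, block]).tocsr()
        labels = la.leiden_cluster(adj, resolution=0.5, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1

    def test_determinism(self):
        rng = np.random.default_rng(3)
        g = la.build_knn_graph(proj(rng.normal(size=(60, 4))), k=6)
        l1 = la.leiden_cluster(g, resolution=1.0, seed=7)
        l2 = la.leiden_cluster(g, resolution=1.0, seed=7)
        assert np.array_equal(l1, l2)

    def test_labels_ordered_by_community_size(self):
        n1, n2 = 12, 6
        adj = sp.block_diag(
            [np.ones((n1, n1)) - np.eye(n1), np.ones((n2, n2)) - np.eye(n2)]
        ).tocsr()
        labels = la.leiden_cluster(adj, resolution=0.5, seed=0)
        assert set(labels[:n1]) == {0} and set(labels[n1:]) == {1}

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            la.leiden_cluster(sp.csr_matrix((0, 0)), resolution=1.0, seed=0)

    def test_permutation_invariance_up_to_relabeling(self, pipeline_result):
        truth_free_labels = pipeline_result.labels
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(truth_free_labels))
        g = pipeline_result.knn[perm][:, perm]
        labels_perm = la.leiden_cluster(
            g, resolution=la.pipeline.DEFAULT_RESOLUTION, seed=0
        )
        assert adjusted_rand_score(truth_free_labels[perm], labels_perm) >= 0.99


class TestTsne:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        p = proj(rng.normal(size=(60, 5)))
        e1 = la.tsne_embed(p, perplexity=10, seed=3)
        e2 = la.tsne_embed(p, perplexity=10, seed=3)
        assert np.array_equal(e1, e2)

    def test_separated_populations_stay_separated(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(40, 5))
        b = rng.normal(size=(40, 5)) + 50.0
        emb = la.tsne_embed(proj(np.vstack([a, b])), perplexity=15, seed=0)
        intra = np.linalg.norm(emb[:40] - emb[:40].mean(axis=0), axis=1).mean()
        centroid_gap = np.linalg.norm(emb[:40].mean(axis=0) - emb[40:].mean(axis=0))
        assert centroid_gap > 2 * intra

    def test_invalid_perplexity_is_error(self):
        with pytest.raises(ValueError):
            la.tsne_embed(proj(np.zeros((10, 2))), perplexity=5, seed=0)


class TestAnnotation:
    def test_planted_populations_annotated_correctly(
        self, pipeline_result, truth_labels
    ):
        # every cluster dominated by a planted population gets that name
        labels = pipeline_result.labels
        ann = pipeline_result.annotations
        pops = truth_labels["population"].to_numpy()
        for cl in np.unique(labels):
            dominant = pd.Series(pops[labels == cl]).mode()[0]
            if dominant != "doublet":
                assert ann[int(cl)] == dominant

    def test_cluster_without_panel_genes_is_unassigned(self):
        counts = np.zeros((8, 3), dtype=int)
        counts[:4, 0] = 9  # Gal+ cluster 0
        counts[:, 2] = 1
        m = make_count_matrix(counts, genes=["Gal", "Ms4a1", "other"])
        labels = np.array([0] * 4 + [1] * 4)
        ann = la.annotate_clusters(labels, m, panel={"Mac I": [("Gal", +1)],
                                                     "B": [("Ms4a1", +1)]})
        assert ann[0] == "Mac I"
        assert ann[1] == "unassigned"

    def test_exact_tie_goes_to_first_panel_entry(self):
        counts = np.array([[5, 5]] * 4)
        m = make_count_matrix(counts, genes=["a", "b"])
        ann = la.annotate_clusters(
            np.zeros(4, int), m, panel={"T1": [("a", +1)], "T2": [("b", +1)]}
        )
        assert ann[0] == "T1"


class TestDotplot:
    def test_absent_gene_gives_zero_frac_and_pseudocount_log(self):
        counts = np.array([[0, 10], [0, 20]])
        m = make_count_matrix(counts, genes=["silent", "loud"])
        nm = la.cpm_normalize(m)
        d = la.dotplot_summary(np.zeros(2, int), nm, ["silent", "loud"])
        silent = d[d["gene"] == "silent"].iloc[0]
        assert silent["frac_expressing"] == 0.0
        assert silent["mean_log_expression"] == -1.0
        assert d[d["gene"] == "loud"]["frac_expressing"].item() == 1.0

    def test_grid_complete_and_fracs_in_unit_interval(self, pipeline_result):
        nm = pipeline_result.normalized
        genes = ["Gal", "Ms4a1", "Cd3e"]
        d = la.dotplot_summary(pipeline_result.labels, nm, genes)
        n_clusters = len(np.unique(pipeline_result.labels))
        assert len(d) == len(genes) * n_clusters
        assert d["frac_expressing"].between(0, 1).all()

    def test_marker_contrast_in_home_cluster(self, pipeline_result, truth_labels):
        nm = pipeline_result.normalized
        labels = pipeline_result.labels
        pops = truth_labels["population"].to_numpy()
        d = la.dotplot_summary(labels, nm, ["Ms4a1"])
        ann = pipeline_result.annotations
        home = [cl for cl, name in ann.items() if name == "B"]
        rows = d.set_index("cluster")["frac_expressing"]
        for cl in rows.index:
            if cl in home:
                assert rows[cl] >= 0.8
            else:
                assert rows[cl] <= 0.3
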