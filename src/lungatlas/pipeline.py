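"""End-to-end orchestration of the atlas analysis.

Stages run in the order the analysis prescribes: cell-level QC
filters, a provisional clustering to flag doublet clusters, removal of
those clusters, then re-normalization, feature selection, PCA,
clustering and (optionally) embedding on the cleaned matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import cluster as cl
from . import normalize as nrm
from . import qc
from .containers import CountMatrix, NormalizedMatrix
from .synthetic import CONTAMINANT_MARKERS, IMMUNE_MARKER

logger = logging.getLogger(__name__)

#: Leiden resolution calibrated once on the default synthetic design so
#: the cleaned atlas resolves its 15 designed populations
DEFAULT_RESOLUTION = 0.2


@dataclass
class PipelineResult:
    matrix: CountMatrix  # cleaned matrix (post QC + doublet removal)
    normalized: NormalizedMatrix
    features: nrm.FeatureSelection
    pca: nrm.PCAProjection
    knn: "object"
    labels: np.ndarray
    embedding: np.ndarray | None
    annotations: dict
    qc_report: qc.QCReport


def run_pipeline(
    m: CountMatrix,
    min_reads: int = qc.MIN_READS,
    min_genes: int = qc.MIN_GENES,
    n_features: int = 500,
    n_pcs: int = 25,
    knn_k: int = 15,
    resolution: float = DEFAULT_RESOLUTION,
    provisional_resolution: float | None = None,
    seed: int = 0,
    compute_embedding: bool = False,
    perplexity: float = 30.0,
    contaminant_markers=CONTAMINANT_MARKERS,
    immune_marker: str = IMMUNE_MARKER,
    marker_panel: dict | None = None,
) -> PipelineResult:
    """Run QC, doublet exclusion, and clustering on a count matrix."""
    filtered, report = qc.filter_cells(m, min_reads=min_reads, min_genes=min_genes)
    if provisional_resolution is None:
        # finer provisional clustering keeps doublet exclusion surgical:
        # rare populations must not merge with a doublet community
        provisional_resolution = 3.0 * resolution

    def _cluster(mat: CountMatrix, res: float):
        nm = nrm.cpm_normalize(mat)
        feats = nrm.fano_feature_select(nm, n_features=n_features)
        pca = nrm.pca_project(nm, feats, k=min(n_pcs, len(feats.selected_genes)))
        graph = cl.build_knn_graph(pca, k=knn_k)
        labels = cl.leiden_cluster(graph, resolution=res, seed=seed)
        return nm, feats, pca, graph, labels

    # provisional pass to find doublet clusters
    _, _, _, _, prov_labels = _cluster(filtered, provisional_resolution)
    flagged = qc.flag_doublet_clusters(
        filtered, prov_labels, contaminant_markers, immune_marker=immune_marker
    )
    cleaned, report = qc.remove_doublet_clusters(filtered, prov_labels, flagged, report)
    logger.info(
        "doublet exclusion: %d clusters flagged, %d cells removed",
        len(flagged), report.n_doublets_removed,
    )

    # final pass on the cleaned matrix
    nm, feats, pca, graph, labels = _cluster(cleaned, resolution)
    embedding = (
        cl.tsne_embed(pca, perplexity=perplexity, seed=seed)
        if compute_embedding
        else None
    )
    annotations = cl.annotate_clusters(labels, cleaned, panel=marker_panel)
    return PipelineResult(
        matrix=cleaned,
        normalized=nm,
        features=feats,
        pca=pca,
        knn=graph,
        labels=labels,
        embedding=embedding,
        annotations=annotations,
        qc_report=report,
    )


def trajectory_analysis(
    result: PipelineResult,
    cluster_ids,
    early_markers: list[str],
    n_pcs: int = 5,
    n_neighbors: int = 30,
):
    """Pseudotime over the cells of selected clusters.

    The selected clusters' cells are re-projected on their own: the
    atlas-level feature set is kept, but PCA is recomputed within the
    subset so that between-population axes vanish and the
    developmental program dominates the leading components.  A
    trajectory is low-dimensional, so few components (default 5) and a
    generous neighborhood stabilize the diffusion pseudotime.  The
    root is the subset cell scoring highest on the early marker set.

    Returns ``(PseudotimeResult, subset_mask, subset_coordinates)``.
    """
    from sklearn.decomposition import PCA

    from . import trajectory as tj

    subset = np.isin(result.labels, list(np.atleast_1d(cluster_ids)))
    if subset.sum() < 3:
        raise ValueError("selected clusters contain fewer than 3 cells")
    sub_m = result.matrix.subset_cells(subset)
    nm = nrm.cpm_normalize(sub_m)
    gene_idx = [nm.genes.index(g) for g in result.features.selected_genes]
    X = nm.log_view[:, gene_idx]
    k = min(n_pcs, X.shape[0] - 1, X.shape[1])
    coords = PCA(k, svd_solver="full").fit_transform(X)
    root_local = tj.select_root_cell(nm, np.arange(sub_m.n_cells), early_markers)
    pt = tj.compute_pseudotime(coords, root_local, n_neighbors=n_neighbors)
    return pt, subset, coords
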