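"""kNN graph, Leiden communities, t-SNE embedding and marker annotation.

The cell graph is a symmetrized (edge-union) k-nearest-neighbor graph
in PC space with unit edge weights; neighbor ties break by ascending
cell index so the graph is reproducible.  Communities come from Leiden
modularity optimization; the 2-D embedding from t-SNE initialized on
the first two principal components.  Clusters are annotated against a
marker panel by the fraction of cells expressing each rule gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.manifold import TSNE

from .containers import CountMatrix, NormalizedMatrix
from .normalize import PCAProjection

logger = logging.getLogger(__name__)

#: default panel: cell type -> [(gene, direction)]; order breaks ties
DEFAULT_MARKER_PANEL = {
    "Mac I": [("Gal", +1)],
    "Mac III": [("Car4", +1), ("Itgax", +1)],
    "Mac II": [("Itgax", +1), ("Car4", -1)],
    "Mac IV": [("C1qa", +1)],
    "Mac V": [("Plac8", +1)],
    "cDC1": [("Itgae", +1)],
    "cDC2": [("Cd209a", +1)],
    "Mig-DC": [("Mreg", +1)],
    "B": [("Ms4a1", +1)],
    "T": [("Cd3e", +1)],
    "NK": [("Gzma", +1)],
    "ILC2": [("Areg", +1)],
    "mast": [("Mcpt4", +1)],
    "basophil": [("Mcpt8", +1)],
    "neutrophil": [("Retnlg", +1)],
}


def build_knn_graph(p: PCAProjection, k: int = 15) -> sp.csr_matrix:
    """Symmetrized Euclidean kNN graph in PC space (unit weights).

    Each cell contributes directed edges to its k nearest neighbors
    (ties broken by ascending cell index); the union of directed edges
    gives the symmetric adjacency, so every node ends with degree >= k.
    """
    X = p.coordinates
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    # brute-force with lexsort keeps exact ties deterministic
    rows, cols = [], []
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = (
            np.sum(X[start:stop] ** 2, axis=1)[:, None]
            - 2.0 * X[start:stop] @ X.T
            + np.sum(X**2, axis=1)[None, :]
        )
        for i in range(start, stop):
            di = d2[i - start].copy()
            di[i] = np.inf
            order = np.lexsort((np.arange(n), di))
            rows.extend([i] * k)
            cols.extend(order[:k])
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    adj = ((adj + adj.T) > 0).astype(float)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj


def leiden_cluster(
    g: sp.spmatrix, resolution: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Leiden community labels, ordered by decreasing community size."""
    g = sp.coo_matrix(g)
    n = g.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    mask = g.row < g.col  # undirected: keep each edge once
    edges = list(zip(g.row[mask].tolist(), g.col[mask].tolist()))
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # relabel so community 0 is the largest; ties by original label
    ids, sizes = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -sizes))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[x] for x in raw], dtype=int)


def tsne_embed(
    p: PCAProjection, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE of the PC coordinates, initialized from the first two PCs."""
    X = p.coordinates
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity={perplexity} too large for {n} cells")
    init = X[:, :2].copy()
    init = init / max(np.std(init[:, 0]), 1e-12) * 1e-4  # small-variance PCA init
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init=init,
        random_state=seed,
        n_jobs=1,
    )
    return ts.fit_transform(X)


@dataclass
class ClusteringResult:
    knn_graph: sp.csr_matrix
    labels: np.ndarray
    embedding: np.ndarray | None
    parameters: dict


def _frac_expressing(m: CountMatrix, labels: np.ndarray, gene: str) -> dict[int, float]:
    col = m.gene_index(gene)
    pos = np.asarray(m.counts[:, col].todense()).ravel() > 0
    return {int(cl): float(np.mean(pos[labels == cl])) for cl in np.unique(labels)}


def annotate_clusters(
    labels: np.ndarray,
    m: CountMatrix,
    panel: dict | None = None,
    score_floor: float = 0.25,
) -> dict[int, str]:
    """Assign each cluster the panel type with the best rule score.

    A rule's score is the mean over its genes of the direction-signed
    fraction of cluster cells expressing the gene (raw count > 0; a
    negative direction contributes ``1 - frac``).  Clusters whose best
    score is below ``score_floor`` are "unassigned"; exact ties go to
    the type listed first in the panel.
    """
    panel = panel if panel is not None else DEFAULT_MARKER_PANEL
    labels = np.asarray(labels)
    fracs: dict[str, dict[int, float]] = {}
    resolved_any = False
    for rules in panel.values():
        for gene, _ in rules:
            if gene in fracs:
                continue
            if gene in m.genes:
                fracs[gene] = _frac_expressing(m, labels, gene)
                resolved_any = True
            else:
                logger.warning("panel gene %r not in matrix; skipped", gene)
    if not resolved_any:
        raise ValueError("no panel gene resolves against the matrix")

    out: dict[int, str] = {}
    for cl in np.unique(labels):
        best_name, best_score = None, -np.inf
        for name, rules in panel.items():
            terms = []
            for gene, direction in rules:
                if gene not in fracs:
                    continue
                f = fracs[gene][int(cl)]
                terms.append(f if direction > 0 else 1.0 - f)
            if not terms:
                continue
            score = float(np.mean(terms))
            if score > best_score:  # strict: ties keep earlier panel entry
                best_name, best_score = name, score
            elif score == best_score:
                logger.info("cluster %s: tie between %s and %s", cl, best_name, name)
        out[int(cl)] = best_name if best_score >= score_floor else "unassigned"
    return out


def dotplot_summary(
    labels: np.ndarray, nm: NormalizedMatrix, genes: list[str]
) -> pd.DataFrame:
    """Per (gene, cluster) fraction expressing and mean log10 CPM."""
    labels = np.asarray(labels)
    m = nm.source
    recs = []
    for gene in genes:
        col = m.gene_index(gene)
        pos = np.asarray(m.counts[:, col].todense()).ravel() > 0
        logv = nm.log_view[:, col]
        for cl in np.unique(labels):
            sel = labels == cl
            recs.append(
                (gene, int(cl), float(np.mean(pos[sel])), float(np.mean(logv[sel])))
            )
    return pd.DataFrame(
        recs, columns=["gene", "cluster", "frac_expressing", "mean_log_expression"]
    )
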