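"""CPM normalization, per-mouse Fano-factor feature selection, and PCA.

Counts are normalized to counts per million per cell; all log
transforms use log10 with a pseudocount of 0.1 CPM.  Feature selection
follows the per-replicate Fano-factor scheme: within every mouse the
variance/mean ratio of each gene's CPM is ranked, a gene is "high
Fano" in a mouse when its rank is within ``high_rank_cutoff``, and the
500 genes high in the most mice are kept (support-majority ordering).
The selected log-CPM submatrix, gene-centered, is projected onto the
top 25 principal components with a deterministic solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


class FeatureSelectionError(ValueError):
    pass


def cpm_normalize(m: CountMatrix) -> NormalizedMatrix:
    """Normalize each cell's counts to counts per million.

    All-zero cells (not expected after QC) pass through as zeros with
    a warning.
    """
    counts = np.asarray(m.counts.todense(), dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero cells passed through CPM unchanged", zero.sum())
        totals[zero] = 1.0
    cpm = counts / totals[:, None] * 1e6
    return NormalizedMatrix(cpm=cpm, source=m)


@dataclass
class FeatureSelection:
    """Outcome of the per-mouse Fano-factor gene selection."""

    selected_genes: list[str]
    per_mouse_fano_rank: pd.DataFrame  # gene x mouse rank (1 = highest Fano)
    support: pd.Series  # per gene: number of mice where rank <= cutoff
    n_features: int
    high_rank_cutoff: int


def fano_feature_select(
    nm: NormalizedMatrix,
    n_features: int = 500,
    high_rank_cutoff: int = 1000,
    min_cells_per_mouse: int = 5,
) -> FeatureSelection:
    """Select genes with a high Fano factor (Var/Mean of CPM) in most mice.

    Genes are ordered by (support descending, mean within-mouse rank
    ascending, symbol ascending); genes with zero mean in a mouse get
    that mouse's worst rank.  Mice with fewer than
    ``min_cells_per_mouse`` cells are skipped with a warning; fewer
    than two usable mice is an error.
    """
    mouse_ids = nm.cells["mouse_id"].to_numpy()
    usable = []
    for m in pd.unique(mouse_ids):
        n = int((mouse_ids == m).sum())
        if n >= min_cells_per_mouse:
            usable.append(m)
        else:
            logger.warning("mouse %s has %d cells (<%d); skipped", m, n, min_cells_per_mouse)
    if len(usable) < 2:
        raise FeatureSelectionError(
            f"need >= 2 mice with >= {min_cells_per_mouse} cells; have {len(usable)}"
        )

    genes = nm.genes
    n_genes = len(genes)
    ranks = {}
    for m in usable:
        sub = nm.cpm[mouse_ids == m]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fano = np.where(mean > 0, var / mean, -np.inf)
        # rank 1 = highest Fano; zero-mean genes share the worst ranks
        order = np.argsort(-fano, kind="stable")
        r = np.empty(n_genes, dtype=float)
        r[order] = np.arange(1, n_genes + 1)
        r[mean == 0] = n_genes
        ranks[m] = r
    rank_table = pd.DataFrame(ranks, index=genes)
    support = (rank_table <= high_rank_cutoff).sum(axis=1)

    order_df = pd.DataFrame(
        {
            "support": support,
            "mean_rank": rank_table.mean(axis=1),
            "symbol": rank_table.index,
        }
    ).sort_values(
        ["support", "mean_rank", "symbol"], ascending=[False, True, True], kind="stable"
    )
    n_eligible = int((support > 0).sum())
    n_take = min(n_features, n_eligible) if n_eligible else min(n_features, n_genes)
    if n_take < n_features:
        logger.warning("only %d eligible genes; requested %d", n_take, n_features)
    selected = order_df.index[:n_take].tolist()
    return FeatureSelection(
        selected_genes=selected,
        per_mouse_fano_rank=rank_table,
        support=support,
        n_features=n_features,
        high_rank_cutoff=high_rank_cutoff,
    )


@dataclass
class PCAProjection:
    coordinates: np.ndarray  # cell x k
    component_loadings: np.ndarray  # gene x k
    explained_variance: np.ndarray  # length k, non-increasing
    genes: list[str]


def pca_project(
    nm: NormalizedMatrix, features: FeatureSelection, k: int = 25
) -> PCAProjection:
    """PCA of the log-CPM matrix restricted to the selected genes.

    Genes are centered but not unit-scaled.  The sign of each component
    is fixed so its largest-magnitude loading is positive, making the
    projection deterministic.
    """
    sel = features.selected_genes
    if k > len(sel):
        raise ValueError(f"k={k} exceeds the {len(sel)} selected features")
    gene_idx = [nm.genes.index(g) for g in sel]
    X = nm.log_view[:, gene_idx]
    k_eff = min(k, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # gene x k

    # deterministic sign convention
    for j in range(k_eff):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    return PCAProjection(
        coordinates=coords,
        component_loadings=loadings,
        explained_variance=pca.explained_variance_,
        genes=list(sel),
    )
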