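"""One-vs-rest Kolmogorov-Smirnov marker ranking.

For each gene, the two-sample KS statistic compares the CPM
distribution in a target cluster against all remaining cells (or a
second cluster).  Genes are ranked by the statistic; the log2 fold
change of mean CPM (with a 0.1 pseudocount in numerator and
denominator) accompanies each row.  The KS statistic is invariant
under monotone transforms, so CPM and log-CPM give identical ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .containers import NormalizedMatrix

#: below this per-group size the exact KS p-value is used
EXACT_P_MAX_N = 25


def _group_masks(labels, cluster_id, versus=None):
    labels = np.asarray(labels)
    in_mask = labels == cluster_id
    if versus is None:
        out_mask = ~in_mask
    else:
        out_mask = labels == versus
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise ValueError(
            f"cluster {cluster_id!r} vs {'rest' if versus is None else versus!r}: "
            "each group needs >= 2 cells"
        )
    return in_mask, out_mask


def ks_one_vs_rest(
    nm: NormalizedMatrix, labels, cluster_id, versus=None
) -> pd.DataFrame:
    """Per-gene two-sample KS statistic and p-value, cluster vs rest.

    The p-value is exact when the smaller group has <= 25 cells
    (matching small-cluster marker tables) and asymptotic otherwise.
    """
    in_mask, out_mask = _group_masks(labels, cluster_id, versus)
    a = nm.cpm[in_mask]
    b = nm.cpm[out_mask]
    method = "exact" if min(a.shape[0], b.shape[0]) <= EXACT_P_MAX_N else "asymp"
    stats = np.empty(a.shape[1])
    pvals = np.empty(a.shape[1])
    for g in range(a.shape[1]):
        res = ks_2samp(a[:, g], b[:, g], method=method)
        stats[g], pvals[g] = res.statistic, res.pvalue
    return pd.DataFrame(
        {"gene": nm.genes, "ks_statistic": stats, "p_value": pvals}
    )


def log2_fold_change(
    nm: NormalizedMatrix, labels, cluster_id, versus=None, eps: float = 0.1
) -> pd.DataFrame:
    """log2((mean CPM in cluster + eps) / (mean CPM in comparison + eps))."""
    in_mask, out_mask = _group_masks(labels, cluster_id, versus)
    mean_in = nm.cpm[in_mask].mean(axis=0)
    mean_out = nm.cpm[out_mask].mean(axis=0)
    lfc = np.log2((mean_in + eps) / (mean_out + eps))
    return pd.DataFrame({"gene": nm.genes, "log2_fold_change": lfc})


def deg_table(
    nm: NormalizedMatrix,
    labels,
    cluster_id,
    top_n: int = 35,
    versus=None,
    eps: float = 0.1,
) -> pd.DataFrame:
    """Ranked marker table for one cluster (one-vs-rest or vs a cluster).

    Rows sort by KS statistic descending, then p ascending, then |lfc|
    descending, then gene symbol; in one-vs-rest mode only upregulated
    genes (lfc > 0) are kept before truncation to ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.asarray(labels)
    known = set(np.unique(labels))
    if cluster_id not in known:
        raise KeyError(f"unknown cluster id {cluster_id!r}")
    if versus is not None and versus not in known:
        raise KeyError(f"unknown cluster id {versus!r}")
    ks = ks_one_vs_rest(nm, labels, cluster_id, versus)
    lfc = log2_fold_change(nm, labels, cluster_id, versus, eps=eps)
    table = ks.merge(lfc, on="gene")
    if versus is None:
        table = table[table["log2_fold_change"] > 0]
    table = table.assign(_abs_lfc=table["log2_fold_change"].abs()).sort_values(
        ["ks_statistic", "p_value", "_abs_lfc", "gene"],
        ascending=[False, True, False, True],
        kind="stable",
    )
    return table.drop(columns="_abs_lfc").head(top_n).reset_index(drop=True)
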