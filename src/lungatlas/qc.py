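"""Cell-level quality filters and cluster-level doublet exclusion.

Cells with fewer than 50,000 uniquely mapped reads or fewer than 400
detected genes are discarded (strict less-than; equality retains).
Doublets are then removed at the cluster level: after a provisional
clustering, clusters whose cells jointly express the pan-immune marker
(Cd45/Ptprc) together with mutually exclusive non-immune lineage
markers (Epcam, Cdh5, Col6a2, ...) are flagged and dropped, and the
cleaned matrix is re-clustered.  Every removed cell is accounted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

logger = logging.getLogger(__name__)

MIN_READS = 50_000
MIN_GENES = 400

DISPOSITIONS = ("kept", "fail_reads", "fail_genes", "fail_both", "doublet")


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Bookkeeping for every cell removed by QC.

    ``n_final = n_after_filters - n_doublets_removed``; a cell failing
    both read and gene filters increments both failure counters but is
    removed once.  ``dispositions`` partitions the input cells.
    """

    n_input: int
    n_fail_reads: int
    n_fail_genes: int
    n_after_filters: int
    n_doublets_removed: int = 0
    dispositions: pd.Series | None = None  # indexed by cell_id

    @property
    def n_final(self) -> int:
        return self.n_after_filters - self.n_doublets_removed


def filter_cells(
    m: CountMatrix, min_reads: int = MIN_READS, min_genes: int = MIN_GENES
) -> tuple[CountMatrix, QCReport]:
    """Drop cells below the read- or gene-detection thresholds."""
    reads = m.cells["mapped_reads"].to_numpy()
    genes = m.cells["n_genes"].to_numpy()
    fail_reads = reads < min_reads
    fail_genes = genes < min_genes
    keep = ~(fail_reads | fail_genes)

    disp = np.full(m.n_cells, "kept", dtype=object)
    disp[fail_reads & ~fail_genes] = "fail_reads"
    disp[fail_genes & ~fail_reads] = "fail_genes"
    disp[fail_reads & fail_genes] = "fail_both"
    report = QCReport(
        n_input=m.n_cells,
        n_fail_reads=int(fail_reads.sum()),
        n_fail_genes=int(fail_genes.sum()),
        n_after_filters=int(keep.sum()),
        dispositions=pd.Series(disp, index=m.cells["cell_id"].to_numpy()),
    )
    logger.info(
        "QC filters: %d input, %d fail reads, %d fail genes, %d retained",
        report.n_input, report.n_fail_reads, report.n_fail_genes,
        report.n_after_filters,
    )
    return m.subset_cells(keep), report


def flag_doublet_clusters(
    m: CountMatrix,
    labels: np.ndarray,
    contaminant_markers,
    immune_marker: str = "Ptprc",
    frac_threshold: float = 0.5,
) -> set[int]:
    """Flag clusters that look like immune/non-immune doublets.

    A cluster is flagged if at least ``frac_threshold`` of its cells
    co-express (raw count > 0) the immune marker and at least one
    contaminant marker, or if the cluster's mean CPM of any contaminant
    marker exceeds that of the immune marker.  Markers absent from the
    gene list are skipped with a warning; if none resolve, raise.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_cells:
        raise QCError("labels not aligned to cells")
    present = [g for g in contaminant_markers if g in m.genes]
    skipped = [g for g in contaminant_markers if g not in m.genes]
    if skipped:
        logger.warning("contaminant markers absent from matrix: %s", skipped)
    if immune_marker not in m.genes:
        raise QCError(f"immune marker {immune_marker!r} not in gene list")
    if not present:
        raise QCError("no contaminant marker resolves against the gene list")

    counts = m.counts
    imm_col = m.gene_index(immune_marker)
    con_cols = [m.gene_index(g) for g in present]
    imm_pos = np.asarray(counts[:, imm_col].todense()).ravel() > 0
    con_pos = np.asarray((counts[:, con_cols] > 0).sum(axis=1)).ravel() > 0

    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0

    flagged: set[int] = set()
    for cl in np.unique(labels):
        sel = labels == cl
        frac_joint = float(np.mean(imm_pos[sel] & con_pos[sel]))
        sub = counts[sel]
        sub_tot = totals[sel][:, None]
        imm_cpm = float(np.mean(np.asarray(sub[:, imm_col].todense()).ravel() / totals[sel] * 1e6))
        con_cpm = np.asarray(sub[:, con_cols].todense()) / sub_tot * 1e6
        max_con_cpm = float(con_cpm.mean(axis=0).max())
        if frac_joint >= frac_threshold or max_con_cpm > imm_cpm:
            flagged.add(int(cl))
            logger.info(
                "cluster %s flagged as doublet (joint fraction %.2f, "
                "max contaminant CPM %.1f vs immune %.1f)",
                cl, frac_joint, max_con_cpm, imm_cpm,
            )
    return flagged


def remove_doublet_clusters(
    m: CountMatrix, labels: np.ndarray, flagged: set[int], report: QCReport
) -> tuple[CountMatrix, QCReport]:
    """Drop cells in flagged clusters and update the QC report."""
    labels = np.asarray(labels)
    is_doublet = np.isin(labels, list(flagged)) if flagged else np.zeros(m.n_cells, bool)
    report.n_doublets_removed = int(is_doublet.sum())
    if report.dispositions is not None:
        ids = m.cells["cell_id"].to_numpy()[is_doublet]
        report.dispositions.loc[ids] = "doublet"
    return m.subset_cells(~is_doublet), report


def qc_accounting(report: QCReport) -> pd.DataFrame:
    """Emit the arithmetic chain n_input -> n_after_filters -> n_final.

    Raises on an internally inconsistent report.
    """
    if report.n_doublets_removed > report.n_after_filters:
        raise QCError(
            f"doublets removed ({report.n_doublets_removed}) exceed cells "
            f"after filters ({report.n_after_filters})"
        )
    if report.n_after_filters > report.n_input:
        raise QCError("more cells after filtering than in input")
    if report.dispositions is not None:
        if len(report.dispositions) != report.n_input:
            raise QCError("dispositions do not partition the input cells")
        vc = report.dispositions.value_counts()
        removed_by_filter = report.n_input - report.n_after_filters
        if int(vc.reindex(["fail_reads", "fail_genes", "fail_both"]).fillna(0).sum()) != removed_by_filter:
            raise QCError("disposition counts inconsistent with filter totals")
    return pd.DataFrame(
        {
            "stage": ["input", "after_filters", "final"],
            "n_cells": [report.n_input, report.n_after_filters, report.n_final],
            "n_removed": [
                0,
                report.n_input - report.n_after_filters,
                report.n_doublets_removed,
            ],
        }
    )
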