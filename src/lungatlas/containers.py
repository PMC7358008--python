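"""Core in-memory containers for the pipeline.

The root object is :class:`CountMatrix`: a cells x genes matrix of
non-negative integer read counts together with aligned per-cell metadata
(mouse of origin, sex, developmental timepoint, uniquely mapped reads,
genes detected) and unique gene symbols.  Normalization produces a
:class:`NormalizedMatrix` holding counts-per-million values and their
log10 view with a pseudocount of 0.1 CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TIMEPOINTS = ("E18.5", "P1", "P7", "P21")
SEXES = ("female", "male", "unknown")

#: pseudocount, in CPM units, used for every log10 transform in the pipeline
LOG_PSEUDOCOUNT = 0.1

CELL_COLUMNS = ["cell_id", "mouse_id", "sex", "timepoint", "mapped_reads", "n_genes"]


class ValidationError(ValueError):
    """Raised when an input matrix or annotation violates an invariant."""


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


@dataclass
class CountMatrix:
    """Cells x genes integer count matrix with aligned annotations.

    Parameters
    ----------
    counts
        Sparse or dense matrix of shape ``(n_cells, n_genes)``; entries
        must be non-negative integers (read pairs assigned per gene).
    cells
        DataFrame with one row per cell and columns ``cell_id``,
        ``mouse_id``, ``sex``, ``timepoint``, ``mapped_reads``,
        ``n_genes``.  ``n_genes`` is always recomputed from the matrix.
    genes
        Ordered unique gene symbols, one per matrix column.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.genes = [str(g) for g in self.genes]
        self.cells = self.cells.reset_index(drop=True).copy()
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cells) != n_cells:
            raise ValidationError(
                f"cell annotation has {len(self.cells)} rows but matrix has "
                f"{n_cells} cells"
            )
        if len(self.genes) != n_genes:
            raise ValidationError(
                f"gene annotation has {len(self.genes)} entries but matrix has "
                f"{n_genes} genes"
            )
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if data.size and np.any(data != np.floor(data)):
            raise ValidationError("count matrix contains non-integer entries")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols are not unique")
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns and c != "n_genes"]
        if missing:
            raise ValidationError(f"cell annotation missing columns: {missing}")
        if self.cells["cell_id"].duplicated().any():
            raise ValidationError("cell ids are not unique")
        bad_tp = set(self.cells["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        # n_genes is derived from the matrix, never trusted from annotation
        derived = self._detected_genes()
        if "n_genes" in self.cells.columns:
            stated = self.cells["n_genes"].to_numpy()
            n_mismatch = int(np.sum(stated != derived))
            if n_mismatch:
                logger.warning(
                    "n_genes annotation disagreed with the matrix for %d cells; "
                    "recomputed from nonzero counts",
                    n_mismatch,
                )
        self.cells["n_genes"] = derived

    def _detected_genes(self) -> np.ndarray:
        nz = self.counts.copy()
        nz.eliminate_zeros()
        return np.diff(nz.indptr)

    # -- conveniences ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.genes.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not present") from None

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given cells."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx],
            cells=self.cells.iloc[idx],
            genes=list(self.genes),
        )


@dataclass
class NormalizedMatrix:
    """Counts-per-million values plus their log10(cpm + 0.1) view.

    ``cpm`` rows sum to 1e6 (all-zero cells pass through as zeros);
    ``log_view`` of a zero entry is exactly ``log10(0.1) == -1``.
    """

    cpm: np.ndarray
    source: CountMatrix
    pseudocount: float = LOG_PSEUDOCOUNT
    _log_view: np.ndarray | None = field(default=None, repr=False)

    @property
    def log_view(self) -> np.ndarray:
        if self._log_view is None:
            self._log_view = np.log10(self.cpm + self.pseudocount)
        return self._log_view

    @property
    def cells(self) -> pd.DataFrame:
        return self.source.cells

    @property
    def genes(self) -> list[str]:
        return self.source.genes

    @property
    def n_cells(self) -> int:
        return self.cpm.shape[0]
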