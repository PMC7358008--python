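"""Reading and writing pipeline objects in plain-text standard formats.

Count matrices live on disk in matrix-market convention for expression
data: genes x cells in the ``.mtx`` file, transposed to cells x genes in
memory so that per-cell operations are row-wise.  Cell and gene
annotations are TSV files with header rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CELL_COLUMNS, CountMatrix, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ["cell_id", "mouse_id", "sex", "timepoint", "mapped_reads"]


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Resolve gene-symbol collisions by suffixing .1, .2, ... deterministically."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            logger.warning("duplicate gene symbol %r renamed to %r", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_counts(matrix_path, cell_annot_path, gene_annot_path) -> CountMatrix:
    """Read a matrix-market counts file plus TSV annotations.

    The ``.mtx`` file is genes x cells; annotations must match its
    dimensions.  ``n_genes`` is recomputed from the matrix, overriding
    any annotation column (a mismatch is logged, not fatal).
    """
    matrix_path = Path(matrix_path)
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.csr_matrix(mat).T  # genes x cells on disk -> cells x genes
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.data.size and np.any(mat.data != np.floor(mat.data)):
            raise ValidationError(
                f"{matrix_path.name}: matrix contains non-integer entries"
            )
        mat = mat.astype(np.int64)

    cells = pd.read_csv(cell_annot_path, sep="\t", dtype={"cell_id": str, "mouse_id": str})
    genes_df = pd.read_csv(gene_annot_path, sep="\t")
    if "gene_symbol" not in genes_df.columns:
        raise ValidationError(f"{gene_annot_path}: missing 'gene_symbol' column")
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"{cell_annot_path}: missing columns {missing}")
    if len(cells) != mat.shape[0]:
        raise ValidationError(
            f"{cell_annot_path}: {len(cells)} cells annotated but matrix "
            f"{matrix_path.name} has {mat.shape[0]}"
        )
    if len(genes_df) != mat.shape[1]:
        raise ValidationError(
            f"{gene_annot_path}: {len(genes_df)} genes annotated but matrix "
            f"{matrix_path.name} has {mat.shape[1]}"
        )
    symbols = _dedupe_symbols([str(s) for s in genes_df["gene_symbol"]])
    cells = cells.copy()
    cells["sex"] = cells.get("sex", "unknown").fillna("unknown")
    return CountMatrix(counts=mat, cells=cells, genes=symbols)


def write_counts(m: CountMatrix, out_dir) -> Path:
    """Write a CountMatrix as matrix.mtx (genes x cells) + TSV annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), m.counts.T.astype(np.int64))
    m.cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_symbol": m.genes}).to_csv(
        out_dir / "genes.tsv", sep="\t", index=False
    )
    return out_dir


def read_counts_dir(in_dir) -> CountMatrix:
    in_dir = Path(in_dir)
    return read_counts(in_dir / "matrix.mtx", in_dir / "cells.tsv", in_dir / "genes.tsv")


def write_table(table: pd.DataFrame, path) -> Path:
    """Write any tabular result as a UTF-8 TSV with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
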