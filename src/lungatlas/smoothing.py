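"""Second-order kNN-graph smoothing of the expression matrix.

One smoothing round replaces each cell's value by the mean over the
cell and its graph neighbors (row-normalized adjacency with a
self-loop); two rounds propagate information exactly to second-order
neighbors.  The operation is for visualizing low or noisy genes only:
clustering and differential expression always use unsmoothed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import LOG_PSEUDOCOUNT, NormalizedMatrix


@dataclass
class SmoothedMatrix:
    values: np.ndarray  # cell x gene smoothed CPM
    rounds: int
    genes: list[str]

    @property
    def log_view(self) -> np.ndarray:
        return np.log10(self.values + LOG_PSEUDOCOUNT)


def smoothing_operator(g: sp.spmatrix) -> sp.csr_matrix:
    """Row-normalized (A + I): each row averages a cell with its neighbors."""
    a = sp.csr_matrix(g, dtype=float)
    a = a + sp.identity(a.shape[0], format="csr")
    inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ a


def smooth_matrix(
    nm: NormalizedMatrix | np.ndarray, g: sp.spmatrix, rounds: int = 2
) -> SmoothedMatrix:
    """Smooth the CPM matrix ``rounds`` times over the cell graph.

    Accepts a NormalizedMatrix or a raw cell x gene array.  A constant
    gene vector is a fixed point; an isolated cell keeps its value.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if isinstance(nm, NormalizedMatrix):
        values = nm.cpm
        genes = list(nm.genes)
    else:
        values = np.asarray(nm, dtype=float)
        genes = [f"g{j}" for j in range(values.shape[1])]
    if values.shape[0] != g.shape[0]:
        raise ValueError(
            f"graph has {g.shape[0]} cells but matrix has {values.shape[0]}"
        )
    op = smoothing_operator(g)
    out = values.copy()
    for _ in range(rounds):
        out = op @ out
    return SmoothedMatrix(values=np.asarray(out), rounds=rounds, genes=genes)
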