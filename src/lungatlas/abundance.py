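"""Developmental abundance, proliferation fractions, and B-cell
germline-identity cumulative curves.

Composition over time expresses each annotated cell type as a
percentage of all immune cells at its timepoint (optionally of a
restricted compartment such as macrophages/monocytes).  Proliferation
is detection-based: a cell is proliferative when it expresses at least
``min_markers_detected`` of the proliferation markers (Mki67, Mcm5) at
raw count > 0.  Germline identity tables (per-cell V/J similarity to
the germline reference) are summarized as empirical CDFs with a
somatic-hypermutation flag on the median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

PROLIFERATION_MARKERS = ("Mki67", "Mcm5")


def composition_over_time(
    cell_types: np.ndarray,
    cells: pd.DataFrame,
    restrict_to: list[str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per (timepoint, cell type).

    The denominator is all typed cells at the timepoint, or only the
    ``restrict_to`` types when given (e.g. the five macrophage/monocyte
    states).  ``log10_percent`` uses a 0.01% floor for display.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    tps = cells["timepoint"].to_numpy()
    recs = []
    for tp in pd.unique(tps):
        sel = tps == tp
        types_here = cell_types[sel]
        if restrict_to is not None:
            keep = np.isin(types_here, restrict_to)
            types_here = types_here[keep]
        total = len(types_here)
        if total == 0:
            logger.warning("timepoint %s has no cells in scope; omitted", tp)
            continue
        for ct, n in pd.Series(types_here).value_counts().items():
            pct = 100.0 * n / total
            recs.append((tp, ct, int(n), pct, np.log10(max(pct, 1e-2))))
    return pd.DataFrame(
        recs, columns=["timepoint", "cell_type", "n_cells", "percent", "log10_percent"]
    )


def proliferation_fraction(
    m: CountMatrix,
    cell_types: np.ndarray,
    compartment: list[str],
    prolif_markers=PROLIFERATION_MARKERS,
    min_markers_detected: int = 1,
) -> pd.DataFrame:
    """Fraction of proliferating cells per timepoint within a compartment.

    A cell is proliferative iff at least ``min_markers_detected`` of
    the marker genes have raw count > 0.
    """
    cols = [m.gene_index(g) for g in prolif_markers if g in m.genes]
    missing = [g for g in prolif_markers if g not in m.genes]
    if missing:
        logger.warning("proliferation markers missing: %s", missing)
    if not cols:
        raise ValueError("no proliferation marker resolves against the matrix")
    detected = np.asarray((m.counts[:, cols] > 0).sum(axis=1)).ravel()
    is_prolif = detected >= min_markers_detected

    cell_types = np.asarray(cell_types, dtype=object)
    in_comp = np.isin(cell_types, compartment)
    tps = m.cells["timepoint"].to_numpy()
    recs = []
    for tp in pd.unique(tps):
        sel = (tps == tp) & in_comp
        n = int(sel.sum())
        if n == 0:
            continue
        recs.append((tp, n, float(np.mean(is_prolif[sel]))))
    return pd.DataFrame(recs, columns=["timepoint", "n_cells", "fraction_proliferating"])


def germline_identity_cdf(
    table: pd.DataFrame, shm_threshold: float = 0.98
) -> tuple[pd.DataFrame, bool]:
    """Cumulative cell-fraction curves of V and J germline identity.

    Returns a long-form table (locus, identity, cumulative_fraction)
    where ``cumulative_fraction`` at identity x is the fraction of
    cells with identity <= x, plus ``shm_flag``: True when the median
    identity of either locus drops below ``shm_threshold`` (evidence
    of somatic hypermutation).
    """
    if len(table) == 0:
        raise ValueError("empty germline identity table")
    recs = []
    shm_flag = False
    for locus, colname in (("V", "v_identity"), ("J", "j_identity")):
        vals = np.sort(np.asarray(table[colname], float))
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"{colname} outside [0, 1]")
        cum = np.arange(1, len(vals) + 1) / len(vals)
        recs.extend((locus, v, c) for v, c in zip(vals, cum))
        if float(np.median(vals)) < shm_threshold:
            shm_flag = True
    return (
        pd.DataFrame(recs, columns=["locus", "identity", "cumulative_fraction"]),
        shm_flag,
    )
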