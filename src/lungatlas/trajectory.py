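"""Pseudotime and scalar-potential attractor analysis.

Diffusion pseudotime orders cells of selected clusters from a root
cell.  The pseudotime is then interpolated as a scalar potential on a
regular grid over the 2-D embedding, restricted to grid nodes near
actual cells; local maxima of the potential mark attractor states and
the 2-D gradient gives the developmental vector field.  Because a
scalar potential has zero curl, rotational flows (e.g. a self-renewing
population) cannot be represented by this construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray  # per subset cell, min-max scaled to [0, 1]
    root_cell: int  # index within the subset
    subset_index: np.ndarray  # indices of subset cells in the full matrix
    unreachable: np.ndarray  # subset cells off the root's component


def compute_pseudotime(
    coordinates: np.ndarray,
    root_cell: int,
    subset: np.ndarray | None = None,
    n_neighbors: int = 15,
) -> PseudotimeResult:
    """Diffusion pseudotime of the subset's cells from a root cell.

    ``coordinates`` are PC coordinates for all cells; ``subset`` is a
    boolean mask or index array choosing the cells to order (default
    all).  ``root_cell`` indexes the full matrix and must lie in the
    subset.  Values are min-max scaled so the root is at 0.
    """
    import anndata as ad
    import scanpy as sc

    n = coordinates.shape[0]
    if subset is None:
        subset_idx = np.arange(n)
    else:
        subset_idx = np.asarray(subset)
        if subset_idx.dtype == bool:
            subset_idx = np.flatnonzero(subset_idx)
    where = np.flatnonzero(subset_idx == root_cell)
    if where.size == 0:
        raise ValueError("root cell is not in the selected subset")
    root_local = int(where[0])
    m = len(subset_idx)
    if m == 1:
        return PseudotimeResult(
            np.zeros(1), root_local, subset_idx, np.zeros(1, bool)
        )

    X = np.asarray(coordinates[subset_idx], dtype=np.float64)
    adata = ad.AnnData(X=X)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, m - 1), use_rep="X")
    sc.tl.diffmap(adata)
    adata.uns["iroot"] = root_local
    sc.tl.dpt(adata)
    pt = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    unreachable = ~np.isfinite(pt)
    if unreachable.any():
        logger.warning("%d cells unreachable from the root", unreachable.sum())
    finite = pt[~unreachable]
    lo, hi = finite.min(), finite.max()
    if hi > lo:
        pt = (pt - lo) / (hi - lo)
    else:
        pt = np.where(unreachable, pt, 0.0)
    return PseudotimeResult(pt, root_local, subset_idx, unreachable)


def select_root_cell(
    nm, subset: np.ndarray, early_markers: list[str]
) -> int:
    """Pick the subset cell with the highest mean log-CPM of early markers."""
    subset_idx = np.asarray(subset)
    if subset_idx.dtype == bool:
        subset_idx = np.flatnonzero(subset_idx)
    cols = [nm.genes.index(g) for g in early_markers if g in nm.genes]
    if not cols:
        raise ValueError("no early marker resolves against the matrix")
    score = nm.log_view[np.ix_(subset_idx, cols)].mean(axis=1)
    return int(subset_idx[int(np.argmax(score))])


@dataclass
class PotentialField:
    xs: np.ndarray  # nx grid coordinates
    ys: np.ndarray  # ny grid coordinates
    populated: np.ndarray  # (nx, ny) bool
    potential: np.ndarray  # (nx, ny), NaN off the populated mask
    maxima: list = field(default_factory=list)  # [(ix, iy, value)] desc by value
    gradient: np.ndarray | None = None  # (nx, ny, 2)
    gradient_defined: np.ndarray | None = None  # (nx, ny, 2) bool


def interpolate_potential(
    embedding: np.ndarray,
    pseudotime: np.ndarray,
    nx: int = 50,
    ny: int = 50,
    radius_factor: float = 1.5,
) -> PotentialField:
    """Interpolate pseudotime onto a grid restricted to populated areas.

    A node is populated when at least one cell lies within
    ``radius_factor`` grid spacings; its potential is the
    inverse-distance-weighted mean of the pseudotimes of cells within
    that radius (a cell exactly on the node contributes its own value).
    """
    emb = np.asarray(embedding, float)
    pt = np.asarray(pseudotime, float)
    if emb.shape[0] < 3:
        raise ValueError("need at least 3 cells to build a potential field")
    xmin, ymin = emb.min(axis=0)
    xmax, ymax = emb.max(axis=0)
    if xmax == xmin or ymax == ymin:
        raise ValueError("degenerate bounding box: cells are collinear/identical")
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    spacing = max(xs[1] - xs[0], ys[1] - ys[0])
    radius = radius_factor * spacing

    tree = cKDTree(emb)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    neighbor_lists = tree.query_ball_point(nodes, r=radius)

    populated = np.zeros(nx * ny, bool)
    potential = np.full(nx * ny, np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        populated[i] = True
        d = np.linalg.norm(emb[nbrs] - nodes[i], axis=1)
        exact = d < 1e-12
        if exact.any():
            potential[i] = pt[np.asarray(nbrs)[exact]].mean()
        else:
            w = 1.0 / d
            potential[i] = np.average(pt[nbrs], weights=w)
    return PotentialField(
        xs=xs,
        ys=ys,
        populated=populated.reshape(nx, ny),
        potential=potential.reshape(nx, ny),
    )


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_local_maxima(f: PotentialField) -> list[tuple[int, int, float]]:
    """Local maxima of the potential over populated 8-neighborhoods.

    A node is a maximum when its potential is >= every populated
    8-neighbor and strictly greater than at least one.  A connected
    plateau of equal potential counts once (its lowest row-major node)
    iff every populated node bordering the plateau is strictly lower;
    a constant field therefore has no maxima.  Maxima are returned
    sorted by potential descending.
    """
    nx, ny = f.potential.shape
    pop = f.populated
    pot = f.potential
    visited = np.zeros((nx, ny), bool)
    maxima = []
    for i in range(nx):
        for j in range(ny):
            if not pop[i, j] or visited[i, j]:
                continue
            # flood-fill the equal-potential plateau containing (i, j)
            val = pot[i, j]
            stack = [(i, j)]
            plateau = []
            visited[i, j] = True
            border_vals = []
            while stack:
                ci, cj = stack.pop()
                plateau.append((ci, cj))
                for di, dj in _NEIGHBOR_OFFSETS:
                    ni, nj = ci + di, cj + dj
                    if not (0 <= ni < nx and 0 <= nj < ny) or not pop[ni, nj]:
                        continue
                    if pot[ni, nj] == val:
                        if not visited[ni, nj]:
                            visited[ni, nj] = True
                            stack.append((ni, nj))
                    else:
                        border_vals.append(pot[ni, nj])
            if border_vals and max(border_vals) < val:
                rep = min(plateau)  # lowest row-major index represents the plateau
                maxima.append((rep[0], rep[1], float(val)))
    maxima.sort(key=lambda t: (-t[2], t[0], t[1]))
    f.maxima = maxima
    return maxima


def gradient_field(f: PotentialField) -> np.ndarray:
    """2-D gradient of the potential on the populated mask.

    Central differences where both axis neighbors are populated,
    one-sided where only one is, zero (flagged undefined) where
    neither.  Vectors point toward increasing pseudotime.
    """
    nx, ny = f.potential.shape
    dx = f.xs[1] - f.xs[0]
    dy = f.ys[1] - f.ys[0]
    grad = np.zeros((nx, ny, 2))
    defined = np.zeros((nx, ny, 2), bool)
    pop = f.populated
    pot = f.potential
    for i in range(nx):
        for j in range(ny):
            if not pop[i, j]:
                continue
            for axis, (d, lim) in enumerate(((dx, nx), (dy, ny))):
                lo = (i - 1, j) if axis == 0 else (i, j - 1)
                hi = (i + 1, j) if axis == 0 else (i, j + 1)
                has_lo = lo[axis] >= 0 and pop[lo]
                has_hi = hi[axis] < lim and pop[hi]
                if has_lo and has_hi:
                    grad[i, j, axis] = (pot[hi] - pot[lo]) / (2 * d)
                    defined[i, j, axis] = True
                elif has_hi:
                    grad[i, j, axis] = (pot[hi] - pot[i, j]) / d
                    defined[i, j, axis] = True
                elif has_lo:
                    grad[i, j, axis] = (pot[i, j] - pot[lo]) / d
                    defined[i, j, axis] = True
    f.gradient = grad
    f.gradient_defined = defined
    return grad
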