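"""Pseudotime over the gradient macrophage population and its
attractor states.

Diffusion pseudotime orders the cells of the developmental-gradient
population from a root cell (the cell scoring highest on the early
program).  The pseudotime is then interpolated as a scalar potential
on a grid over a 2-D embedding of those cells; local maxima of the
potential mark attractor states and its gradient gives the vector
field of developmental flow.
"""

import numpy as np
from scipy.stats import spearmanr

import lungatlas as la

matrix, truth = la.generate_atlas(seed=0)
result = la.run_pipeline(matrix, seed=0)

grad_clusters = [cl for cl, n in result.annotations.items() if n == "Mac II"]
early_program = truth.gradient_genes[:15]
pt, subset, coords = la.trajectory_analysis(
    result, grad_clusters, early_markers=early_program
)
print(f"trajectory over {int(subset.sum())} cells of cluster(s) {grad_clusters}")

td = truth.cell_data.set_index("cell_id")
latent = td.loc[result.matrix.cells["cell_id"], "latent_time"].to_numpy()[subset]
keep = ~np.isnan(latent)
rho = spearmanr(pt.pseudotime[keep], latent[keep]).statistic
print(f"Spearman(pseudotime, planted latent time) = {rho:.3f}")

# scalar potential on the subset's own 2-D view (first two components)
field = la.interpolate_potential(coords[:, :2], pt.pseudotime, nx=30, ny=30)
maxima = la.find_local_maxima(field)
la.gradient_field(field)
print(f"grid nodes populated by cells: {int(field.populated.sum())}/900")
print(f"local pseudotime maxima (attractor states): {len(maxima)}")
for ix, iy, val in maxima[:5]:
    print(f"  node ({ix:2d},{iy:2d})  potential {val:.3f}")
# Arrows of the gradient field point toward increasing pseudotime, so
# attractors are the sinks of the reversed field.
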