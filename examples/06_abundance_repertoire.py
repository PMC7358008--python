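"""Quantify composition over development, proliferation, and B-cell
germline identity.

Composition is expressed per timepoint as a percentage of immune
cells (or of the macrophage/monocyte compartment only).  A cell
counts as proliferating when it expresses Mki67 or Mcm5.  B-cell
receptor germline identity close to 1.0 for the V and J segments
indicates the absence of somatic hypermutation.
"""

import lungatlas as la
from lungatlas.synthetic import MACROPHAGE_POPULATIONS

matrix, truth = la.generate_atlas(seed=0)
result = la.run_pipeline(matrix, seed=0)

types = [result.annotations[c] for c in result.labels]
mm = list(MACROPHAGE_POPULATIONS)

comp = la.composition_over_time(types, result.matrix.cells, restrict_to=mm)
print("macrophage/monocyte composition over development (percent of m/m):")
pivot = comp.pivot(index="cell_type", columns="timepoint", values="percent")
print(pivot[["E18.5", "P1", "P7", "P21"]].round(1).fillna(0.0).to_string())

prolif = la.proliferation_fraction(result.matrix, types, mm)
print("\nfraction of proliferating (Mki67/Mcm5+) m/m cells:")
print(prolif.to_string(index=False))

# germline identity of a simulated naive B-cell repertoire
table = la.generate_germline_table(300, shm_rate=0.0, seed=0)
curve, shm = la.germline_identity_cdf(table)
print(f"\nnaive repertoire: median V identity "
      f"{table['v_identity'].median():.3f}, hypermutation flag: {shm}")
table2 = la.generate_germline_table(300, shm_rate=0.05, seed=0)
_, shm2 = la.germline_identity_cdf(table2)
print(f"mutated repertoire (5% per-site): hypermutation flag: {shm2}")
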