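import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import lungatlas as la


@pytest.fixture(scope="session")
def default_atlas():
    """Default synthetic atlas (8 mice, 15 populations, 2000 cells), seed 0."""
    return la.generate_atlas(seed=0)


@pytest.fixture(scope="session")
def pipeline_result(default_atlas):
    m, _ = default_atlas
    return la.run_pipeline(m, seed=0)


@pytest.fixture(scope="session")
def truth_labels(default_atlas, pipeline_result):
    """Planted population labels aligned to the cleaned matrix's cells."""
    _, truth = default_atlas
    td = truth.cell_data.set_index("cell_id")
    return td.loc[pipeline_result.matrix.cells["cell_id"]]


def make_count_matrix(counts, mouse_ids=None, timepoints=None, genes=None,
                      mapped_reads=None):
    """Small CountMatrix built from a dense array for unit tests."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "mouse_id": mouse_ids if mouse_ids is not None else ["m1"] * n,
            "sex": ["female"] * n,
            "timepoint": timepoints if timepoints is not None else ["P1"] * n,
            "mapped_reads": mapped_reads if mapped_reads is not None else counts.sum(axis=1),
            "n_genes": (counts > 0).sum(axis=1),
        }
    )
    gene_names = genes if genes is not None else [f"g{j}" for j in range(g)]
    return la.CountMatrix(counts=sp.csr_matrix(counts), cells=cells, genes=gene_names)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5.0, size=(12, 8))
    return make_count_matrix(
        counts,
        mouse_ids=["m1"] * 6 + ["m2"] * 6,
        timepoints=["E18.5"] * 6 + ["P1"] * 6,
    )


def ks_statistic_oracle(a, b):
    """Brute-force two-sample KS statistic: explicit CDF scan over all
    pooled sample points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    points = np.union1d(a, b)
    fa = np.searchsorted(a, points, side="right") / a.size
    fb = np.searchsorted(b, points, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))
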