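import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sctme.io import Dataset, sort_genes_genomically
from sctme.simulate import default_cohort, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """One genomically sorted tiny cohort with ground truth, shared
    session-wide (read-only)."""
    ds, truth = generate_cohort(default_cohort("tiny"), seed=11)
    ds, _ = sort_genes_genomically(ds)
    return ds, truth


def make_dataset(counts, conditions=None, major_types=None, sample_ids=None,
                 chromosomes=None, starts=None):
    """Small hand-built Dataset helper for unit tests."""
    counts = sp.csr_matrix(np.asarray(counts))
    n_cells, n_genes = counts.shape
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "sample_id": sample_ids or ["s1"] * n_cells,
        "condition": conditions or ["TNBC"] * n_cells,
        "major_type": major_types or ["Epithelial"] * n_cells,
    })
    cells["minor_type"] = cells["major_type"]
    genes = pd.DataFrame({
        "gene_id": [f"g{j}" for j in range(n_genes)],
        "chromosome": chromosomes or ["chr1"] * n_genes,
        "start": starts or [(j + 1) * 1000 for j in range(n_genes)],
    })
    genes["end"] = genes["start"] + 100
    return Dataset(counts=counts, cells=cells.set_index("cell_id"),
                   genes=genes.set_index("gene_id"))
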