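import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snde.containers import CellCountMatrix, DonorDesign
from snde.simulate import SimulationParams, generate_dataset


def make_matrix(dense, gene_ids=None, donors=None, cell_types=None, doublets=None):
    """Build a CellCountMatrix from a dense array with minimal metadata."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "barcode": [f"BC{j}" for j in range(n_cells)],
            "donor_id": donors if donors is not None else ["D0"] * n_cells,
            "cell_type": cell_types if cell_types is not None else ["T"] * n_cells,
            "is_doublet": doublets if doublets is not None else [False] * n_cells,
        }
    )
    return CellCountMatrix(sp.csr_matrix(dense), np.asarray(gene_ids, dtype=object), meta)


def make_design(donor_conditions: dict) -> DonorDesign:
    return DonorDesign(
        pd.DataFrame(
            {
                "donor_id": list(donor_conditions),
                "condition": list(donor_conditions.values()),
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 4+4-donor cohort, small but with all QC artifacts present."""
    params = SimulationParams(
        n_case=4,
        n_control=4,
        n_genes=300,
        cell_type_profile={"Exc": 60, "Micro": 15},
        de_fraction=0.1,
        de_lfc=1.5,
        seed=123,
    )
    matrix, design, truth = generate_dataset(params)
    return params, matrix, design, truth
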