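import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from allelicdyn import SimConfig, simulate_experiment
from allelicdyn.datamodel import AllelicCountMatrix


@pytest.fixture(scope="session")
def small_experiment():
    """A small mixed-category experiment shared across read-only tests."""
    cfg = SimConfig(
        n_genes=60, n_cells_per_sample=80, n_replicates_per_genotype=3,
        depth_mean=25.0,
        fraction_persistent_cis=0.25, fraction_persistent_trans=0.25,
        fraction_dynamic_cis=0.1, fraction_dynamic_trans=0.1,
        seed=11,
    )
    return simulate_experiment(cfg)


def make_acm(b6, cast, total=None, genes=None, cells=None):
    """Assemble an AllelicCountMatrix from dense arrays."""
    b6 = np.asarray(b6)
    cast = np.asarray(cast)
    if total is None:
        total = b6 + cast
    n_g, n_c = b6.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_g)]
    cells = cells if cells is not None else [f"c{j}" for j in range(n_c)]
    return AllelicCountMatrix(
        pd.Index(genes), pd.Index(cells),
        sparse.csr_matrix(b6), sparse.csr_matrix(cast), sparse.csr_matrix(total),
    )


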