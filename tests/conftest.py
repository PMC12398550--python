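import numpy as np
import pytest
import scipy.sparse as sp

from oligomap.containers import CountMatrix
from oligomap.simulate import SimulationConfig, simulate_reference, simulate_target


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small but structured fixture: 4 classes, quick to simulate and train on."""
    return SimulationConfig(
        n_classes=4, n_genes=200, cells_per_class=60, markers_per_class=8, seed=11
    )


@pytest.fixture(scope="session")
def reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def target(small_cfg, reference):
    _, _, truth = reference
    return simulate_target(small_cfg, truth)


def make_count_matrix(dense, gene_ids=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    return CountMatrix(
        values=sp.csr_matrix(dense),
        gene_ids=gene_ids or [f"G{i}" for i in range(n_genes)],
        barcodes=barcodes or [f"C{j}" for j in range(n_cells)],
    )
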