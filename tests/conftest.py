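import numpy as np
import pytest

from pipebench import SCDataset, SimConfig, simulate_dataset


@pytest.fixture
def tiny_dataset() -> SCDataset:
    """4 genes x 3 cells with one all-zero gene and labels."""
    counts = np.array([
        [0, 0, 0],
        [1, 2, 3],
        [4, 0, 1],
        [2, 2, 2],
    ], dtype=float)
    return SCDataset(
        counts=counts,
        gene_ids=("g1", "g2", "g3", "g4"),
        cell_ids=("c1", "c2", "c3"),
        labels=("A", "A", "B"),
        name="tiny",
    )


@pytest.fixture
def sim_dataset() -> SCDataset:
    """Small simulated dataset with clear group structure."""
    cfg = SimConfig(n_genes=100, n_cells=60, n_groups=3, lfc=2.0,
                    dispersion=0.05, seed=3)
    return simulate_dataset(cfg, name="sim")
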