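"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from xdosage import SimulationConfig, simulate_population
from xdosage.data import AllelicCountMatrix


@pytest.fixture(scope="session")
def small_random_xci():
    """Random-XCI population, bimodal silencing degree (naive + complete)."""
    cfg = SimulationConfig(
        n_cells=400, n_genes_autosomal=600, n_genes_x=120,
        xci_mode="random",
        xci_degree=("mixture", ((0.5, ("point", 0.0)), (0.5, ("point", 1.0)))),
        seed=101)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def graded_rxci():
    """Random-XCI population with uniformly graded silencing (tuning data)."""
    cfg = SimulationConfig(n_cells=400, n_genes_autosomal=600, n_genes_x=120,
                           xci_mode="random", seed=202)
    return simulate_population(cfg)


@pytest.fixture()
def toy_matrix():
    """Hand-sized matrix with known values for arithmetic checks."""
    genes = pd.DataFrame(
        {"chrom": ["1", "1", "X", "X", "X"],
         "escapee": [False] * 5},
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"))
    cells = pd.DataFrame(
        {"sex": ["XX", "XX"], "lineage": "t", "timepoint": 0},
        index=pd.Index(["c0", "c1"], name="cell_id"))
    maternal = np.array([[2, 1], [3, 0], [4, 5], [1, 5], [0, 5]], dtype=float)
    paternal = np.array([[2, 1], [1, 0], [4, 5], [3, 5], [2, 5]], dtype=float)
    total = (maternal + paternal).astype(np.int64)
    return AllelicCountMatrix(maternal, paternal, total, genes, cells)
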