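import numpy as np
import pandas as pd
import pytest

from ccitraj import ExpressionMatrix, LigandReceptorTable, generate_lineage


@pytest.fixture(scope="session")
def small_lineage():
    """A small two-branch lineage used across tests (session-cached)."""
    return generate_lineage(n_cells=180, n_genes=80, n_branches=2, noise_sd=0.2, seed=7)


@pytest.fixture
def tiny_matrix():
    """20 cells x 6 genes, two groups, with ligand/receptor genes planted."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0.0, 3.0, size=(20, 6))
    values[:10, 0] = 5.0  # ligand L1 in group a
    values[10:, 1] = 5.0  # receptor R1 in group b
    values[:10, 2] = 4.0  # ligand L2 in group a
    values[10:, 3] = 0.5  # receptor R2 below validity threshold in group b
    genes = ["L1", "R1", "L2", "R2", "G5", "G6"]
    mat = ExpressionMatrix(values, [f"c{i:02d}" for i in range(20)], genes)
    groups = np.array(["a"] * 10 + ["b"] * 10)
    return mat, groups


@pytest.fixture
def three_pairs():
    return LigandReceptorTable(
        pd.DataFrame(
            [
                ("L1", "R1", "p1"),
                ("L2", "R2", "p2"),
                ("L1", "ABSENT", "p3"),
            ],
            columns=["ligand", "receptor", "pair_id"],
        )
    )
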