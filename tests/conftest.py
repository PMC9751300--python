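import numpy as np
import pandas as pd
import pytest

import masp


@pytest.fixture(scope="session")
def grid2x2():
    return masp.SpatialGrid(
        n_rows=2, n_cols=2, resolution_um=400.0,
        specimen_wells={"A": (0, 0), "B": (0, 1), "C": (1, 0), "D": (1, 1)},
    )


@pytest.fixture(scope="session")
def slice_grid():
    """The default tissue-slice grid: 30x30 wells, 208 occupied."""
    return masp.generate_grid()


@pytest.fixture(scope="session")
def small_dataset(slice_grid):
    """A small synthetic dataset shared across unit tests (300 proteins)."""
    truth = masp.make_brain_slice_truth(slice_grid, n_proteins=300, seed=42)
    mat, qcset, truth = masp.generate_dataset(truth, slice_grid, n_proteins=300)
    return mat, qcset, truth


def quant(values, samples=None, features=None, scale_tag="log2_raw"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(m)]
    return masp.QuantMatrix(
        pd.DataFrame(values, index=samples, columns=features), scale_tag=scale_tag
    )
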