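import numpy as np
import pytest
import scipy.sparse as sp

from countform import CountMatrix, SizeFactors


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes × 4 cells with simple hand-checkable totals."""
    arr = np.array(
        [
            [3, 0, 1, 2],
            [0, 5, 0, 0],
            [1, 1, 1, 1],
        ]
    )
    return CountMatrix(sp.csc_matrix(arr))


@pytest.fixture
def unit_size_factors():
    def make(n_cells: int) -> SizeFactors:
        return SizeFactors(np.ones(n_cells), L=1.0, mode="fixed_L")

    return make


@pytest.fixture
def random_sparse_counts():
    """Random 50×30 sparse integer matrix, ~20% density."""
    rng = np.random.default_rng(42)
    arr = rng.poisson(0.5, size=(50, 30)) * rng.integers(0, 2, size=(50, 30))
    return CountMatrix(sp.csc_matrix(arr))
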