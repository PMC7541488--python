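import numpy as np
import pytest

from scregact import ExpressionMatrix, NormState, random_network


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_counts():
    """5 genes x 4 cells of raw counts with one low-count cell."""
    values = np.array([
        [10, 0, 3, 100],
        [0, 5, 2, 50],
        [7, 1, 0, 25],
        [3, 0, 1, 10],
        [0, 0, 4, 15],
    ], dtype=float)
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(5)],
                            [f"c{i}" for i in range(4)],
                            norm_state=NormState.RAW_COUNTS)


@pytest.fixture
def log_matrix(rng):
    """50 genes x 30 samples of log-scale Gaussian expression."""
    values = rng.normal(6.0, 1.0, (50, 30))
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(50)],
                            [f"s{i}" for i in range(30)],
                            norm_state=NormState.LOG2_NORMALIZED)


@pytest.fixture
def toy_network():
    return random_network(n_tfs=6, targets_per_tf=12, seed=7)
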