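import numpy as np
import pytest

from dnentropy import ExpressionMatrix, RegNetwork


@pytest.fixture
def genes8():
    return [f"G{i + 1}" for i in range(8)]


@pytest.fixture
def small_expr():
    """4 genes x 6 timepoints, fully observed, non-degenerate."""
    rng = np.random.default_rng(12345)
    times = np.arange(0.0, 60.0, 10.0)
    return ExpressionMatrix(
        ["A", "B", "C", "D"], times, rng.normal(size=(4, times.size))
    )


@pytest.fixture
def star_network():
    """Hub H with three leaves; undirected degree 3 at the hub."""
    return RegNetwork.from_edges(["H", "L1", "L2", "L3"], [("H", "L1"), ("H", "L2"), ("H", "L3")])


def star_corr(rho: float = 0.5) -> np.ndarray:
    """Correlation matrix giving every pair the same |corr|."""
    n = 4
    c = np.full((n, n), rho)
    np.fill_diagonal(c, 1.0)
    return c


@pytest.fixture
def star_expr():
    rng = np.random.default_rng(7)
    times = np.arange(0.0, 100.0, 10.0)
    return ExpressionMatrix(
        ["H", "L1", "L2", "L3"], times, rng.normal(size=(4, times.size))
    )
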