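import numpy as np
import pytest

from zassoc import make_table


@pytest.fixture
def table_2x2():
    """phi = 10/sqrt(600) = 0.408248..."""
    return make_table([[3, 2], [1, 4]], ["a", "abar"], ["b", "bbar"])


@pytest.fixture
def table_3x2():
    """Worked example: z = 0.258199 rows-given-cols, 0.333333 transposed."""
    return make_table([[2, 1], [1, 2], [2, 2]], ["A1", "A2", "A3"], ["B1", "B2"])


@pytest.fixture
def table_diag():
    return make_table([[5, 0], [0, 5]], ["A1", "A2"], ["B1", "B2"])


@pytest.fixture
def product_table():
    """Exact outer product: 100 * outer((0.3, 0.7), (0.4, 0.6))."""
    return make_table(
        100 * np.outer([0.3, 0.7], [0.4, 0.6]), ["A1", "A2"], ["B1", "B2"]
    )


def random_table(rng, k, n, concentration=1.0, total=100.0, integral=False):
    p = rng.dirichlet(np.full(k * n, concentration)).reshape(k, n)
    counts = total * p
    if integral:
        counts = np.floor(counts) + 1  # keep strictly positive cells
    return make_table(
        counts,
        [f"A{i}" for i in range(k)],
        [f"B{j}" for j in range(n)],
    )
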