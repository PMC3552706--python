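import numpy as np
import pytest

from lorenzgini.ranking import ContingencyTable
from lorenzgini.synthetic import generate_worked_example_model

# Range x class count tables used throughout: a three-range table whose
# first two rows are class-permutations of each other (class-order bias),
# and a pair of four-range tables with identical pure rows in different
# vertical orders (range-order bias).
TABLE1_COUNTS = np.array([[4, 6, 30], [6, 30, 4], [0, 4, 16]])
TABLE2_LEFT = np.array([[3, 0, 0], [0, 88, 0], [4, 0, 0], [0, 0, 5]])
TABLE2_RIGHT = np.array([[3, 0, 0], [4, 0, 0], [0, 88, 0], [0, 0, 5]])


@pytest.fixture
def table1():
    return ContingencyTable(TABLE1_COUNTS.copy())


@pytest.fixture
def table2_left():
    return ContingencyTable(TABLE2_LEFT.copy())


@pytest.fixture
def table2_right():
    return ContingencyTable(TABLE2_RIGHT.copy())


@pytest.fixture(scope="session")
def worked_model():
    return generate_worked_example_model()


def random_table(rng, max_m=6, max_n=5):
    """A random valid contingency table (no all-zero rows)."""
    m = int(rng.integers(1, max_m + 1))
    n = int(rng.integers(2, max_n + 1))
    while True:
        counts = rng.integers(0, 30, size=(m, n))
        if counts.sum() > 0 and (counts.sum(axis=1) > 0).all():
            return ContingencyTable(counts)
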