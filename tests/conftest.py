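import numpy as np
import pytest

from emscape.incidence import IncidenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220516)


def matrix_from_rows(rows, age_class="total"):
    """Build an IncidenceMatrix from a list of 0/1 row tuples."""
    occ = np.asarray(rows, dtype=bool)
    species = [f"sp{i + 1}" for i in range(occ.shape[0])]
    sites = [f"s{j + 1}" for j in range(occ.shape[1])]
    return IncidenceMatrix(occ, species, sites, age_class)


@pytest.fixture
def nested_3x3():
    """Perfectly nested 3 x 3 matrix."""
    return matrix_from_rows([(1, 1, 1), (1, 1, 0), (1, 0, 0)])


@pytest.fixture
def block_diagonal():
    return matrix_from_rows(
        [(1, 1, 0, 0), (1, 1, 0, 0), (0, 0, 1, 1), (0, 0, 1, 1)]
    )


def random_matrix(rng, n_species, n_sites, fill=0.4):
    """Random incidence matrix with no empty rows or columns."""
    while True:
        occ = rng.random((n_species, n_sites)) < fill
        if occ.any(axis=1).all() and occ.any(axis=0).all():
            return matrix_from_rows(occ)
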