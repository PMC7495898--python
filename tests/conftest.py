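import warnings

import numpy as np
import pytest

from dnahotspot.structure_io import parse_pdb
from dnahotspot.synthetic_fixtures import (
    PlantedTableSpec,
    ToyComplexSpec,
    make_planted_table,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_bundle():
    """Standard toy complex: 12-residue helix beside an 8-bp duplex at a
    3.5 A closest heavy-atom gap; (pdb text, ground-truth keys, Complex)."""
    return make_toy_complex(ToyComplexSpec(
        helix_length=12, dna_base_pairs=8, approach_distance=3.5, seed=1))


@pytest.fixture(scope="session")
def toy_complex(toy_bundle):
    return toy_bundle[2]


@pytest.fixture(scope="session")
def toy_truth(toy_bundle):
    return toy_bundle[1]


@pytest.fixture(scope="session")
def far_bundle():
    """Same construction with a 50 A gap: interface must be empty."""
    return make_toy_complex(ToyComplexSpec(
        helix_length=12, dna_base_pairs=8, approach_distance=50.0, seed=1))


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated two-class table a reasonable classifier nails."""
    return make_planted_table(PlantedTableSpec(
        n_samples=200, n_informative=3, n_noise=5, class_shift=3.0, seed=7))


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


TOY_PDB_3ALA = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       2.153   1.062   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.207  1.00 10.00           C
ATOM      6  N   ALA A   2       2.100  -1.200   0.000  1.00 11.00           N
ATOM      7  CA  ALA A   2       3.550  -1.350   0.000  1.00 11.00           C
ATOM      8  C   ALA A   2       4.100  -2.750   0.000  1.00 11.00           C
ATOM      9  O   ALA A   2       5.300  -2.950   0.100  1.00 11.00           O
ATOM     10  CB  ALA A   2       4.150  -0.550   1.150  1.00 11.00           C
ATOM     11  N   ALA A   3       3.250  -3.800   0.000  1.00 12.00           N
ATOM     12  CA  ALA A   3       3.650  -5.200   0.000  1.00 12.00           C
ATOM     13  C   ALA A   3       2.450  -6.150   0.000  1.00 12.00           C
ATOM     14  O   ALA A   3       1.300  -5.750   0.100  1.00 12.00           O
ATOM     15  CB  ALA A   3       4.500  -5.500   1.250  1.00 12.00           C
END
"""


@pytest.fixture()
def three_ala_pdb():
    return TOY_PDB_3ALA
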