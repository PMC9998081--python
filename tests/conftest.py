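import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from foldspot import Complex, Fold, parse_pdb
from foldspot.synthetic import make_helix, make_two_blob, make_two_chain

TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.500   1.000   0.000  1.00 90.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00 90.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00 90.00           C
TER
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      4  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  ALA A   2       4.800   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""

THREE_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  GLY B   1       0.000  10.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA B   2       3.800  10.000   0.000  1.00  0.00           C
TER
ATOM      5  CA  GLY C   1       0.000  20.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def two_residue_pdb():
    return TWO_RESIDUE_PDB


@pytest.fixture
def two_residue_fold():
    return parse_pdb(TWO_RESIDUE_PDB)


@pytest.fixture
def two_model_pdb():
    return TWO_MODEL_PDB


@pytest.fixture
def three_chain_complex():
    cx = Complex(THREE_CHAIN_PDB)
    return cx


@pytest.fixture
def helix60():
    return make_helix(60)


@pytest.fixture
def helix100():
    return make_helix(100)


@pytest.fixture
def two_blob():
    return make_two_blob(20, 20, separation=50.0, seed=0)


@pytest.fixture
def two_chain():
    return make_two_chain(n=10, separation=4.0)


def random_weights(rng, n, symmetric=True):
    """Random nonnegative sparse-ish weight matrix, zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
    if symmetric:
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
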