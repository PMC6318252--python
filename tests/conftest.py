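import numpy as np
import pytest

from poppet import get_preset, make_synthetic_structure


@pytest.fixture(scope="session")
def preset():
    return get_preset("poppet-2018")


@pytest.fixture(scope="session")
def helix():
    return make_synthetic_structure("ideal-helix", n_residues=12, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


MINI_PDB = """\
HELIX    1   1 ALA A    1  ALA A    3  1                                   3
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.673   6.717  -4.155  1.00  0.00           C
ATOM      4  O   ALA A   1       9.580   6.196  -3.896  1.00  0.00           O
ATOM      5  N   ALA A   2      11.066   7.852  -3.589  1.00  0.00           N
ATOM      6  CA  ALA A   2      10.243   8.568  -2.624  1.00  0.00           C
ATOM      7  C   ALA A   2      10.802   9.966  -2.337  1.00  0.00           C
ATOM      8  O   ALA A   2      11.987  10.244  -2.545  1.00  0.00           O
ATOM      9  N   ALA A   3       9.939  10.851  -1.849  1.00  0.00           N
ATOM     10  CA  ALA A   3      10.327  12.222  -1.531  1.00  0.00           C
ATOM     11  C   ALA A   3       9.391  12.834  -0.486  1.00  0.00           C
ATOM     12  O   ALA A   3       8.178  12.575  -0.480  1.00  0.00           O
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path
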