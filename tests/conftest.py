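import numpy as np
import pytest

from confdesign.energy import ForceFieldTables
from confdesign.synthetic import make_toy_hinge_pair, make_toy_structure


@pytest.fixture(scope="session")
def ff():
    return ForceFieldTables()


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(8)


@pytest.fixture()
def hinge_pair():
    return make_toy_hinge_pair(10.0, axis=(0.0, 0.0, 1.0), n_res=14,
                               axis_point=(5.0, 1.0, 0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


SINGLE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.138  -4.905  1.00  0.00           C
END
"""


@pytest.fixture()
def single_residue_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(SINGLE_RESIDUE_PDB)
    return p
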