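"""Shared synthetic fixtures (session-scoped: geometry generation is reused)."""

import numpy as np
import pytest

from reptation import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    return sd.EnsembleSpec(n_helices=3, helix_length=12, linker_length=5, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return sd.make_helix_bundle(small_spec)


@pytest.fixture(scope="session")
def study_spec():
    """Twelve-helix bundle matching the transporter-scale defaults."""
    return sd.EnsembleSpec(seed=5)


@pytest.fixture(scope="session")
def study_bundle(study_spec):
    return sd.make_helix_bundle(study_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 11.00           C
ATOM      3  C   ALA A   1       2.004   1.424   0.000  1.00 12.00           C
ATOM      4  CB  ALA A   1       1.958  -0.772  -1.212  1.00 13.00           C
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 14.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00 15.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.100  1.00 16.00           C
ATOM      8  N   SER A   3       6.191   3.833   0.200  1.00 17.00           N
ATOM      9  CA  SER A   3       7.644   3.855   0.300  1.00 18.00           C
ATOM     10  C   SER A   3       8.212   5.269   0.400  1.00 19.00           C
ATOM     11  OG  SER A   3       8.155   3.112   1.540  1.00 20.00           O
TER      12      SER A   3
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.004   1.424   0.000  1.00 10.00           C
TER       4      ALA A   1
ATOM      5  N   VAL B   1      10.000   0.000   0.000  1.00 10.00           N
ATOM      6  CA  VAL B   1      11.458   0.000   0.000  1.00 10.00           C
ATOM      7  C   VAL B   1      12.004   1.424   0.000  1.00 10.00           C
TER       8      VAL B   1
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60 10.00           C
ATOM      4  C   ALA A   1       2.004   1.424   0.000  1.00 10.00           C
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00 10.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.100  1.00 10.00           C
TER       8      GLY A   2
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture()
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
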