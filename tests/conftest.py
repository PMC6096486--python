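import numpy as np
import pytest

from flexfit.structure import build_ideal_peptide

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1      -0.572   1.337   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.517   0.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       2.146   1.058   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       2.100  -1.189   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.550  -1.320   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       4.250  -0.002   0.285  1.00  0.00           C
ATOM      8  O   ALA A   2       3.626   1.025   0.540  1.00  0.00           O
ATOM      9  CB  ALA A   2       4.010  -2.360   1.020  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue polyalanine alpha helix (read-only)."""
    return build_ideal_peptide("A" * 20, "alpha")


@pytest.fixture(scope="session")
def helix_mixed():
    """Ideal helix with a spread of side-chain chemistries (read-only)."""
    return build_ideal_peptide("AQLMSHKVTA", "alpha")


@pytest.fixture()
def gly_ala(tmp_path):
    path = tmp_path / "gly_ala.pdb"
    path.write_text(GLY_ALA_PDB)
    return path


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
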