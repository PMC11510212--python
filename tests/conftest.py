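"""Shared fixtures: tiny hand-written PDB files and synthetic ensembles."""

import numpy as np
import pytest

from gactdyn.synth import make_pseudo_receptor

# three-residue toy protein, one model (hand-checked against the PDB format)
TOY_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.040   2.804   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.552   2.644   0.100  1.00  0.00           C
ATOM      7  N   SER A   3       6.266   3.762   0.100  1.00  0.00           N
ATOM      8  CA  SER A   3       7.722   3.745   0.200  1.00  0.00           C
ATOM      9  OG  SER A   3       8.231   5.072   0.300  1.00  0.00           O
ENDMDL
END
"""

# protein residue plus a DOI ligand (HETATM) and a water to be excluded
LIGAND_PDB = """\
ATOM      1  N   ARG A 173      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ARG A 173      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  CZ  ARG A 173      12.000  12.000  10.000  1.00  0.00           C
HETATM    4  C1  DOI A 900      15.000  15.000  15.000  1.00  0.00           C
HETATM    5  N1  DOI A 900      16.200  15.000  15.000  1.00  0.00           N
HETATM    6  O   HOH A 950      30.000  30.000  30.000  1.00  0.00           O
END
"""

WATERS_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   WAT A   2       3.000   0.000   0.000  1.00  0.00           O
HETATM    3 NA    NA A   3       6.000   0.000   0.000  1.00  0.00          NA
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def ligand_pdb(tmp_path):
    p = tmp_path / "ligand.pdb"
    p.write_text(LIGAND_PDB)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATERS_PDB)
    return p


@pytest.fixture(scope="session")
def receptor_pair():
    """Small active/inactive pseudo-receptor pair shared across tests."""
    active, gmap_a = make_pseudo_receptor(n_frames=120, activation=True, seed=11)
    inactive, gmap_i = make_pseudo_receptor(n_frames=120, activation=False, seed=12)
    return active, gmap_a, inactive, gmap_i


def rigid_transform(rng):
    """Random proper rotation + translation for invariance tests."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return Q, t


def apply_rigid(frames_coords, Q, t):
    return frames_coords @ Q.T + t
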