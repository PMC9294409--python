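"""Shared fixtures: synthetic archetype complexes and their full records.

Everything is generated programmatically at test time; the expensive
end-to-end records are session-scoped so each archetype is described once.
"""
import numpy as np
import pytest

from ppiface.config import Config, DEFAULT_CONFIG
from ppiface.dataset_pipeline import compute_record
from ppiface.structure_model import Atom, ComplexPair, Residue
from ppiface.synthetic_complexes import SyntheticSpec, generate


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def groove_pair():
    return generate(SyntheticSpec("peptide_in_groove", {}))


@pytest.fixture(scope="session")
def homodimer_pair():
    return generate(SyntheticSpec("flat_homodimer", {}))


@pytest.fixture(scope="session")
def pocket_pair():
    return generate(SyntheticSpec("slab_with_pocket", {"pocket_radius": 3.0}))


@pytest.fixture(scope="session")
def groove_record(groove_pair):
    return compute_record(groove_pair)


@pytest.fixture(scope="session")
def homodimer_record(homodimer_pair):
    return compute_record(homodimer_pair)


def single_atom_residue(chain, seq, coord, name="CA", element="C", resname="GLY"):
    return Residue(chain, seq, "", resname,
                   [Atom(name, element, np.asarray(coord, float))])


@pytest.fixture
def make_residue():
    return single_atom_residue


NMR_PDB = """EXPDTA    SOLUTION NMR
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CA  GLY B   1       3.000   0.000   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       9.458   9.000   9.000  1.00  0.00           C
ATOM      3  C   ALA A   1       9.009   9.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       9.251   9.390   0.000  1.00  0.00           O
ATOM      5  CA  GLY B   1       9.000   9.000   3.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N
ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.60  0.00           N
ATOM      3  N  CALA A   2       1.000   0.000   0.000  0.50  0.00           N
ATOM      4  N  DALA A   2       2.000   0.000   0.000  0.50  0.00           N
ATOM      5  CA  MSE A   3       2.500   1.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY B   1       3.000   0.000   3.000  1.00  0.00           C
HETATM    7  O   HOH B   2       8.000   0.000   3.000  1.00  0.00           O
END
"""


@pytest.fixture
def nmr_pdb_path(tmp_path):
    p = tmp_path / "nmr.pdb"
    p.write_text(NMR_PDB)
    return p


@pytest.fixture
def altloc_pdb_path(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
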