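import numpy as np
import pytest

from mutddg.structure import Atom, ProteinStructure, ResidueID
from mutddg.synth import make_peptide


@pytest.fixture(scope="session")
def helix12():
    return make_peptide("A" * 12, "helix")


@pytest.fixture(scope="session")
def helix_mixed():
    return make_peptide("AAVAAGAAVAAA", "helix")


@pytest.fixture(scope="session")
def gag_extended():
    return make_peptide("GAG", "extended")


@pytest.fixture(scope="session")
def sheet_pair():
    return make_peptide("VTVTVT", "sheet_pair")


@pytest.fixture()
def helix_pdb(tmp_path, helix_mixed):
    from mutddg.structure import write_pdb

    path = tmp_path / "helix.pdb"
    write_pdb(helix_mixed, path)
    return path


def single_atom_structure(name="CA", aa="GLY", xyz=(0.0, 0.0, 0.0)):
    rid = ResidueID("A", 1, "", aa)
    return ProteinStructure([Atom(name, name[0], rid, np.array(xyz, float))])


@pytest.fixture()
def one_atom():
    return single_atom_structure()
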