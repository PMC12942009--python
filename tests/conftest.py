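import numpy as np
import pytest
from hypothesis import settings

from slam.annotation import SubstitutionModel, annotate_structure
from slam.fixtures import make_random_structure, make_toy_complex
from slam.pipeline import structure_as_substructure

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return SubstitutionModel.default()


@pytest.fixture(scope="session")
def toy_structure():
    s = make_random_structure(7, seed=3)
    annotate_structure(s)
    return s


@pytest.fixture(scope="session")
def toy_substructure(toy_structure):
    return structure_as_substructure(toy_structure)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(pocket_residues=5, ligand_atoms=8, seed=2)


def rigid_copy(structure, seed):
    """Rotated + translated copy of a structure, annotations reset."""
    rng = np.random.default_rng(seed)
    M = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(M) < 0:
        M[:, 0] *= -1
    t = rng.normal(size=3) * 10.0
    s2 = structure.copy()
    for a in s2.atoms():
        a.coords = M @ a.coords + t
        a.dabe = None
    for lig in s2.ligands:
        for a in lig.atoms:
            a.coords = M @ a.coords + t
            a.dabe = None
    annotate_structure(s2)
    return s2
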