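import numpy as np
import pytest

from spindock import synthetic
from spindock.geometry import Atom, RigidBody


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_atom_pdb(tmp_path):
    """Minimal hand-written PDB file with three atoms in one chain."""
    text = "\n".join(
        [
            "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       2.500   3.500   4.500  1.00  0.00           C",
            "ATOM      3  C   ALA A   1      -1.250   0.000   9.875  1.00  0.00           C",
            "END",
        ]
    )
    path = tmp_path / "three.pdb"
    path.write_text(text + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One CA with two altLocs: A at occupancy 0.6, B at 0.4."""
    text = "\n".join(
        [
            "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA ASER A   1       1.000   1.000   1.000  0.60  0.00           C",
            "ATOM      3  CA BSER A   1       5.000   5.000   5.000  0.40  0.00           C",
            "END",
        ]
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text + "\n")
    return path


@pytest.fixture
def toy_problem():
    """Deterministic two-body docking scenario with known truth pose."""
    return synthetic.docking_scenario(seed=0)


@pytest.fixture
def helix_body():
    """Isolated single-chain helical body with lysine side chains."""
    return synthetic._helical_body("helix", "A", 24)


def random_body(rng, n_atoms=15, name="rand"):
    atoms = [
        Atom("X", i + 1, "ALA", "CA", "C", rng.uniform(-10, 10, size=3))
        for i in range(n_atoms)
    ]
    return RigidBody(name, atoms)
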