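import numpy as np
import pytest

from mdpost.trajio import Atom, Topology, Trajectory


@pytest.fixture
def toy_topology():
    """Three-residue Cα-only topology."""
    atoms = tuple(
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_index=i + 1, chain="A")
        for i in range(3)
    )
    return Topology(atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20231015)


def make_ca_trajectory(coords: np.ndarray) -> Trajectory:
    """Wrap an (F, N, 3) array as a Cα trajectory with a generic topology."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = tuple(
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_index=i + 1, chain="A")
        for i in range(n)
    )
    return Trajectory(Topology(atoms), coords)
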