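import numpy as np
import pytest

from fluxent import Atom, Trajectory, make_protein_fixture, write_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_atoms():
    """Three residues, alpha carbon plus one heavy and one hydrogen atom each."""
    atoms = []
    for resid, resname in [(1, "MET"), (2, "ALA"), (3, "GLY")]:
        atoms.append(Atom(resid, resname, "N"))
        atoms.append(Atom(resid, resname, "CA"))
        atoms.append(Atom(resid, resname, "HA"))
    return tuple(atoms)


@pytest.fixture
def toy_trajectory(rng, toy_atoms):
    """100-frame trajectory of small fluctuations about a fixed backbone."""
    n_atoms = len(toy_atoms)
    base = rng.uniform(0.0, 10.0, size=(n_atoms, 3))
    coords = base[None] + 0.3 * rng.standard_normal((100, n_atoms, 3))
    return Trajectory(coords, timestep_ns=0.1, atoms=toy_atoms)


@pytest.fixture
def fixture_dir(tmp_path):
    """On-disk synthetic fixture: PDB topology + columnar trajectory."""
    fix = make_protein_fixture(3, 100, seed=5, timestep_ns=0.5)
    return write_fixture(fix, tmp_path / "fix")
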