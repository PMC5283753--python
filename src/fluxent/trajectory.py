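"""Trajectory ingestion, atom selection, and rigid-body alignment.

A :class:`Trajectory` is the raw input of the whole analysis chain: the
Cartesian positions of a fixed set of atoms over ``n_T`` equally spaced
frames, together with the time per frame.  Structures are read from PDB
topologies; coordinates come either from binary MD formats (DCD/XTC, via
MDAnalysis) or from a plain-text columnar dialect defined here so that
fixtures need no binary files.

All rigid-body motion (global rotation + translation) must be removed
before fluctuations are meaningful; :func:`align_frames` superposes every
frame onto a reference frame with a least-squares (Kabsch) fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "Trajectory",
    "read_trajectory",
    "read_columnar",
    "write_columnar",
    "align_frames",
    "select_atoms",
    "write_residue_scalar_pdb",
]

_COLUMNAR_SUFFIXES = {".crd", ".dat", ".txt", ".traj"}


@dataclass(frozen=True)
class Atom:
    """Label of one analysis atom: residue number/name, atom name, chain."""

    resid: int
    resname: str
    name: str
    chain: str = "A"

    @property
    def residue_label(self) -> str:
        return f"{self.resname}{self.resid}"

    def token(self) -> str:
        return f"{self.resname}:{self.resid}:{self.name}:{self.chain}"

    @classmethod
    def from_token(cls, token: str) -> "Atom":
        resname, resid, name, chain = token.split(":")
        return cls(int(resid), resname, name, chain)


@dataclass
class Trajectory:
    """Positions of ``n_atoms`` atoms over ``n_T`` frames.

    Parameters
    ----------
    coords
        Array of shape ``(n_T, n_atoms, 3)`` in Angstrom.
    timestep_ns
        Time between stored frames (ns); total time is ``n_T * timestep_ns``.
    atoms
        One :class:`Atom` label per coordinate column, topology order.
    """

    coords: np.ndarray
    timestep_ns: float
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_T, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but {len(self.atoms)} labels given"
            )
        if not self.timestep_ns > 0:
            raise ValueError("timestep_ns must be positive")
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.timestep_ns

    @property
    def residue_labels(self) -> list[str]:
        return [a.residue_label for a in self.atoms]


# -- selection ---------------------------------------------------------------

_MDA_ALIASES = {
    "alpha carbons": "name CA",
    "ca": "name CA",
    "heavy": "not name H*",
    "all heavy atoms": "not name H*",
    "all": "all",
}


def _mda_selection(spec: str) -> str:
    return _MDA_ALIASES.get(spec.strip().lower(), spec)


def select_atoms(traj: Trajectory, spec: str | Sequence[int]) -> np.ndarray:
    """Resolve a selection against a :class:`Trajectory`'s atom labels.

    Accepts an explicit index sequence or one of the specs understood
    without a topology file: ``"all"``, ``"alpha carbons"``/``"name CA"``,
    ``"heavy"``/``"all heavy atoms"``/``"not name H*"``, or ``"name <X>"``.
    """
    if not isinstance(spec, str):
        idx = np.asarray(spec, dtype=int)
        if idx.size == 0:
            raise ValueError("empty atom selection")
        if idx.min() < 0 or idx.max() >= traj.n_atoms:
            raise IndexError("selection index out of range")
        return idx
    s = spec.strip().lower()
    names = np.array([a.name for a in traj.atoms])
    if s == "all":
        idx = np.arange(traj.n_atoms)
    elif s in ("alpha carbons", "ca", "name ca"):
        idx = np.flatnonzero(names == "CA")
    elif s in ("heavy", "all heavy atoms", "not name h*"):
        idx = np.flatnonzero(~np.char.startswith(names, "H"))
    elif s.startswith("name "):
        idx = np.flatnonzero(names == spec.strip().split(None, 1)[1].upper())
    else:
        raise ValueError(f"unsupported selection for in-memory trajectory: {spec!r}")
    if idx.size == 0:
        raise ValueError(f"selection {spec!r} matched no atoms")
    return idx


# -- readers -----------------------------------------------------------------

def _atoms_from_universe(ag) -> tuple[Atom, ...]:
    out = []
    for a in ag:
        try:
            chain = a.chainID or "A"
        except AttributeError:
            chain = getattr(a, "segid", "A").strip() or "A"
        out.append(Atom(int(a.resid), str(a.resname), str(a.name), str(chain)))
    return tuple(out)


def read_trajectory(
    topology: str | Path,
    trajectory: str | Path,
    selection: str = "alpha carbons",
    timestep_ns: float | None = None,
) -> Trajectory:
    """Read a PDB topology plus a DCD/XTC or columnar coordinate file.

    ``timestep_ns`` overrides (and for the columnar dialect must supply)
    the per-frame time; DCD/XTC metadata is used when present.  Raises
    ``ValueError`` on atom-count mismatch, empty selection, or a missing
    timestep.
    """
    import MDAnalysis as mda

    topology = Path(topology)
    trajectory = Path(trajectory)
    if not topology.exists():
        raise FileNotFoundError(topology)
    if not trajectory.exists():
        raise FileNotFoundError(trajectory)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology))
    columnar = trajectory.suffix.lower() in _COLUMNAR_SUFFIXES
    if columnar:
        atoms_hdr, coords = read_columnar(trajectory)
        if coords.shape[1] != len(u.atoms):
            raise ValueError(
                f"atom-count mismatch: topology has {len(u.atoms)} atoms, "
                f"trajectory rows encode {coords.shape[1]}"
            )
        if timestep_ns is None:
            raise ValueError("timestep_ns is required for columnar trajectories")
        ag = u.select_atoms(_mda_selection(selection))
        if len(ag) == 0:
            raise ValueError(f"selection {selection!r} matched no atoms")
        idx = ag.ix
        return Trajectory(coords[:, idx, :], timestep_ns, _atoms_from_universe(ag))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology), str(trajectory))
    except Exception as exc:  # MDAnalysis raises assorted types on mismatch
        raise ValueError(f"could not combine topology and trajectory: {exc}") from exc
    ag = u.select_atoms(_mda_selection(selection))
    if len(ag) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    if timestep_ns is None:
        dt_ps = getattr(u.trajectory, "dt", 0.0)
        if not dt_ps or dt_ps <= 0:
            raise ValueError("trajectory carries no timestep; pass timestep_ns")
        timestep_ns = dt_ps / 1000.0
    frames = np.array([ag.positions.copy() for _ in u.trajectory], dtype=np.float64)
    return Trajectory(frames, timestep_ns, _atoms_from_universe(ag))


def read_columnar(path: str | Path) -> tuple[tuple[Atom, ...], np.ndarray]:
    """Read the plain-text columnar dialect: a header row of
    ``RESNAME:RESID:NAME:CHAIN`` tokens, then one row of x y z triplets per
    frame."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        atoms = tuple(Atom.from_token(tok) for tok in header)
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if data.shape[1] != 3 * len(atoms):
        raise ValueError(
            f"columnar file has {data.shape[1]} value columns, "
            f"expected {3 * len(atoms)} for {len(atoms)} atoms"
        )
    return atoms, data.reshape(data.shape[0], len(atoms), 3)


def write_columnar(traj: Trajectory, path: str | Path) -> None:
    """Write the columnar dialect; %.17g preserves float64 bit-for-float."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" ".join(a.token() for a in traj.atoms) + "\n")
        np.savetxt(fh, traj.coords.reshape(traj.n_frames, -1), fmt="%.17g")


# -- alignment ---------------------------------------------------------------

def align_frames(
    traj: Trajectory,
    reference: int = 0,
    fit_selection: str | Sequence[int] = "alpha carbons",
) -> Trajectory:
    """Remove rigid-body motion by least-squares superposition.

    Every frame is rotated/translated so that the ``fit_selection`` atoms
    optimally superpose (minimum RMSD, Kabsch solution) onto the same atoms
    of the ``reference`` frame; the transform is applied to all atoms.
    """
    from scipy.spatial.transform import Rotation

    if not 0 <= reference < traj.n_frames:
        raise IndexError(f"reference frame {reference} out of range")
    fit = select_atoms(traj, fit_selection)
    if fit.size < 3:
        raise ValueError("rigid-body fit needs at least 3 atoms")
    ref = traj.coords[reference, fit, :]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    # rank < 2 after centering means (near-)collinear fit atoms
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear; rotation is under-determined")

    out = np.empty_like(traj.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        for k in range(traj.n_frames):
            mob = traj.coords[k, fit, :]
            mob_centroid = mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob - mob_centroid)
            out[k] = rot.apply(traj.coords[k] - mob_centroid) + ref_centroid
    return replace(traj, coords=out)


# -- scalar-per-residue PDB output -------------------------------------------

def write_residue_scalar_pdb(
    topology: str | Path, values: Sequence[float], out: str | Path
) -> None:
    """Write the topology PDB with each atom's B-factor set to its residue's
    scalar (2 decimals, fixed-width column), e.g. for coloring net entropy
    sources and sinks on the structure."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology))
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(u.residues),):
            raise ValueError(
                f"{len(values)} values for {len(u.residues)} residues"
            )
        if not hasattr(u.atoms, "tempfactors"):
            u.add_TopologyAttr("tempfactors")
        for res, v in zip(u.residues, values):
            res.atoms.tempfactors = v
        u.atoms.write(str(out))
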