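"""Per-atom fluctuations about the trajectory-mean position.

After rigid-body alignment each atom fluctuates about a well-defined
equilibrium mean position; the analysis downstream uses the fluctuation
vector ΔR_i(t_k) = R_i(t_k) − R̄_i and, for all entropy estimation, its
magnitude |ΔR_i(t_k)|.  The mean-square fluctuation links directly to the
crystallographic B-factor, B_i = (8π²/3)⟨(ΔR_i)²⟩.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .trajectory import Atom, Trajectory

__all__ = [
    "FluctuationSet",
    "trim_equilibration",
    "compute_fluctuations",
    "mean_square_fluctuation",
    "bfactor",
    "BFACTOR_PREFACTOR",
]

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class FluctuationSet:
    """Mean positions, fluctuation vectors and magnitudes of a trajectory.

    ``vectors`` (frames × atoms × 3, Å) have zero time-mean per atom by
    construction; ``magnitudes`` (frames × atoms, Å) are their Euclidean
    norms and are the series every entropy estimator consumes.
    """

    mean_positions: np.ndarray
    vectors: np.ndarray
    magnitudes: np.ndarray
    timestep_ns: float
    atoms: tuple[Atom, ...]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.vectors.shape[1]

    @property
    def residue_labels(self) -> list[str]:
        return [a.residue_label for a in self.atoms]

    def save(self, path: str | Path) -> None:
        """Serialize all arrays to a compressed .npz container."""
        np.savez_compressed(
            path,
            mean_positions=self.mean_positions,
            vectors=self.vectors,
            magnitudes=self.magnitudes,
            timestep_ns=np.float64(self.timestep_ns),
            atom_tokens=np.array([a.token() for a in self.atoms]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FluctuationSet":
        with np.load(path) as z:
            return cls(
                z["mean_positions"],
                z["vectors"],
                z["magnitudes"],
                float(z["timestep_ns"]),
                tuple(Atom.from_token(t) for t in z["atom_tokens"]),
            )

    def magnitudes_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.magnitudes, columns=self.residue_labels).to_csv(
            path, index=False
        )


def trim_equilibration(traj: Trajectory, n_skip: int) -> Trajectory:
    """Drop the first ``n_skip`` frames (pre-equilibration data)."""
    if n_skip < 0:
        raise ValueError("n_skip must be non-negative")
    if traj.n_frames - n_skip < 2:
        raise ValueError(
            f"n_skip={n_skip} leaves fewer than 2 of {traj.n_frames} frames"
        )
    if n_skip == 0:
        return traj
    return replace(traj, coords=traj.coords[n_skip:])


def compute_fluctuations(traj: Trajectory) -> FluctuationSet:
    """Subtract each atom's time-mean position; store vectors and norms.

    The trajectory must already be rigid-body aligned, otherwise global
    motion contaminates the apparent fluctuations.
    """
    mean_positions = traj.coords.mean(axis=0)
    vectors = traj.coords - mean_positions[None, :, :]
    magnitudes = np.linalg.norm(vectors, axis=2)
    return FluctuationSet(
        mean_positions, vectors, magnitudes, traj.timestep_ns, traj.atoms
    )


def mean_square_fluctuation(fset: FluctuationSet, atom: int) -> float:
    """⟨(ΔR_i)²⟩: time-mean squared fluctuation magnitude of one atom (Å²)."""
    return float(np.mean(fset.magnitudes[:, atom] ** 2))


def bfactor(fset: FluctuationSet, atom: int) -> float:
    """Crystallographic B-factor equivalent, B = (8π²/3)⟨(ΔR)²⟩ (Å²)."""
    return BFACTOR_PREFACTOR * mean_square_fluctuation(fset, atom)
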