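"""Synthetic coupled trajectories with known driver→driven ground truth.

Real MD fluctuation series are not needed to exercise the estimators: a
first-order vector autoregression

    x(t+1) = A x(t) + ε(t),   ε ~ N(0, diag(σ²))

with spectral radius ρ(A) < 1 produces stationary, exponentially
correlated series whose causal structure is exactly the sparsity pattern
of A.  Because the process is Gaussian, transfer entropy has a closed
form from conditional variances (the Granger-causality limit),

    TE(i→j, τ) = ½ ln [ Var(x_j(t+τ) | x_j(t)) / Var(x_j(t+τ) | x_j(t), x_i(t)) ],

which serves as an independent oracle for the histogram estimator.

:func:`make_protein_fixture` embeds such series into a toy alpha-carbon
chain (PDB + 3-D coordinates) so the full pipeline from file reading and
alignment onward can run on fully synthetic data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .trajectory import Atom, Trajectory, write_columnar

__all__ = [
    "Var1Model",
    "simulate_var1",
    "analytic_gaussian_te",
    "stationary_covariance",
    "make_protein_fixture",
    "write_fixture",
]


@dataclass
class Var1Model:
    """Stationary VAR(1) process x(t+1) = A x(t) + ε(t).

    ``coeffs`` is the n × n lag-1 coefficient matrix (spectral radius < 1);
    ``noise_sd`` the innovation SD (scalar or per-series); ``timestep_ns``
    assigns a nominal time per frame so lags can be quoted in ns.
    """

    coeffs: np.ndarray
    noise_sd: float | np.ndarray = 1.0
    n_frames: int = 10000
    seed: int = 0
    timestep_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=np.float64))
        if self.coeffs.shape[0] != self.coeffs.shape[1]:
            raise ValueError("coefficient matrix must be square")
        rho = np.max(np.abs(np.linalg.eigvals(self.coeffs)))
        if rho >= 1.0:
            raise ValueError(f"non-stationary model: spectral radius {rho:.3f} >= 1")
        self._spectral_radius = float(rho)
        sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=np.float64), (self.coeffs.shape[0],)
        )
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be positive")
        self._sd = np.array(sd)

    @property
    def n_series(self) -> int:
        return self.coeffs.shape[0]

    @property
    def spectral_radius(self) -> float:
        return self._spectral_radius

    def burn_in(self) -> int:
        """10× the longest autocorrelation time, −1/ln ρ(A) frames."""
        rho = self._spectral_radius
        if rho <= 0:
            return 0
        return min(int(math.ceil(-10.0 / math.log(rho))), 10_000)


def simulate_var1(model: Var1Model, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the VAR(1), discarding burn-in; returns (n_frames, n_series).

    Deterministic for a fixed ``model.seed`` (or an explicitly passed
    generator)."""
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    burn = model.burn_in()
    total = model.n_frames + burn
    eps = rng.normal(0.0, 1.0, size=(total, model.n_series)) * model._sd
    x = np.zeros((total, model.n_series))
    a = model.coeffs
    prev = np.zeros(model.n_series)
    for t in range(total):
        prev = a @ prev + eps[t]
        x[t] = prev
    return x[burn:]


def stationary_covariance(model: Var1Model) -> np.ndarray:
    """Stationary covariance Σ solving Σ = A Σ Aᵀ + diag(σ²)."""
    from scipy.linalg import solve_discrete_lyapunov

    return solve_discrete_lyapunov(model.coeffs, np.diag(model._sd**2))


def analytic_gaussian_te(model: Var1Model, i: int, j: int, tau_frames: int) -> float:
    """Closed-form Gaussian transfer entropy TE(i→j) at an integer lag.

    Built from the exact stationary covariance of (x_i(t), x_j(t),
    x_j(t+τ)) via Gaussian conditional variances; exact for the model, so
    it is an independent oracle for the histogram estimator.
    """
    if i == j:
        raise ValueError("transfer entropy is defined for distinct series")
    if tau_frames < 1:
        raise ValueError("lag must be at least 1 frame")
    sigma = stationary_covariance(model)
    a_tau = np.linalg.matrix_power(model.coeffs, tau_frames)
    lagged = a_tau @ sigma  # lagged[j, i] = Cov(x_j(t+τ), x_i(t))

    var_jt = sigma[j, j]
    cov_jt_j0 = lagged[j, j]
    cov_jt_i0 = lagged[j, i]

    v_given_j = var_jt - cov_jt_j0**2 / sigma[j, j]
    block = np.array([[sigma[i, i], sigma[i, j]], [sigma[i, j], sigma[j, j]]])
    b = np.array([cov_jt_i0, cov_jt_j0])
    try:
        v_given_ij = var_jt - b @ np.linalg.solve(block, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular conditional covariance") from exc
    if v_given_ij <= 0 or v_given_j <= 0:
        raise ValueError("singular conditional covariance")
    return 0.5 * math.log(v_given_j / v_given_ij)


# -- protein-like fixtures ---------------------------------------------------

@dataclass
class ProteinFixture:
    """A toy chain trajectory plus its causal ground truth."""

    trajectory: Trajectory
    couplings: list[tuple[int, int, float]]
    model: Var1Model
    latent: np.ndarray = field(repr=False, default=None)


def _coupling_matrix(
    n_residues: int,
    couplings: Sequence[tuple[int, int, float]],
    phi: float,
) -> np.ndarray:
    a = np.eye(n_residues) * phi
    seen = set()
    for driver, driven, strength in couplings:
        if not (0 <= driver < n_residues and 0 <= driven < n_residues):
            raise ValueError(f"coupling ({driver}->{driven}) out of range")
        if (driver, driven) in seen:
            raise ValueError(f"duplicate coupling pair ({driver}->{driven})")
        seen.add((driver, driven))
        a[driven, driver] = strength
    return a


def make_protein_fixture(
    n_residues: int,
    n_frames: int,
    couplings: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    phi: float = 0.5,
    noise_sd: float = 1.0,
    timestep_ns: float = 1.0,
    magnitude_offset: float = 0.1,
) -> ProteinFixture:
    """Build a toy alpha-carbon chain whose displacement magnitudes follow
    coupled VAR(1) processes.

    Residue k sits at (3.8k, 0, 0) Å; each frame displaces it by
    (|z_k(t)| + offset) along a random unit vector with a random sign, so
    the empirical mean stays at the base position and the fluctuation
    magnitude tracks |z_k(t)|.  ``couplings`` are (driver, driven,
    strength) triples defining the ground-truth causality.
    """
    a = _coupling_matrix(n_residues, couplings, phi)
    model = Var1Model(a, noise_sd, n_frames, seed, timestep_ns)
    rng = np.random.default_rng(seed)
    z = simulate_var1(model, rng)
    mags = np.abs(z) + magnitude_offset

    directions = rng.normal(size=(n_frames, n_residues, 3))
    directions /= np.linalg.norm(directions, axis=2, keepdims=True)
    base = np.zeros((n_residues, 3))
    base[:, 0] = 3.8 * np.arange(n_residues)
    coords = base[None, :, :] + mags[:, :, None] * directions
    atoms = tuple(Atom(k + 1, "ALA", "CA", "A") for k in range(n_residues))
    traj = Trajectory(coords, timestep_ns, atoms)
    return ProteinFixture(traj, [tuple(c) for c in couplings], model, z)


def write_fixture(fixture: ProteinFixture, outdir: str | Path) -> dict[str, str]:
    """Write the fixture as PDB topology + columnar trajectory +
    ground-truth JSON; returns the paths."""
    import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = fixture.trajectory
    n = traj.n_atoms

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
        )
        u.add_TopologyAttr("names", [a.name for a in traj.atoms])
        u.add_TopologyAttr("resnames", [a.resname for a in traj.atoms])
        u.add_TopologyAttr("resids", [a.resid for a in traj.atoms])
        u.add_TopologyAttr("elements", ["C"] * n)
        u.atoms.positions = traj.coords[0]
        pdb_path = outdir / "fixture.pdb"
        u.atoms.write(str(pdb_path))

    traj_path = outdir / "fixture.traj"
    write_columnar(traj, traj_path)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "couplings": [list(c) for c in fixture.couplings],
                "phi": float(np.diag(fixture.model.coeffs)[0]),
                "seed": fixture.model.seed,
                "timestep_ns": traj.timestep_ns,
                "n_frames": traj.n_frames,
            },
            indent=2,
        )
    )
    return {
        "topology": str(pdb_path),
        "trajectory": str(traj_path),
        "ground_truth": str(truth_path),
    }
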