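"""Static and time-delayed correlations of residue fluctuations.

The time-delayed cross-correlation

    C_ij(τ) = ⟨ΔR_i(t) · ΔR_j(t+τ)⟩ / (⟨ΔR_i²⟩ ⟨ΔR_j²⟩)^{1/2}

is generally asymmetric for τ > 0 (C_ij ≠ C_ji): if residue i drives
residue j, the forward curve C_ij(τ) decays more slowly than C_ji(τ).
At τ = 0 it reduces to the symmetric Pearson correlation map.

Two modes are supported.  ``vector`` correlates the mean-centred 3-D
fluctuation vectors (dot products; can reach −1 for anti-phase motion,
the convention behind the usual dynamic cross-correlation map).
``magnitude`` correlates the mean-centred scalar fluctuation magnitudes,
the same series the entropy estimators consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fluctuation import FluctuationSet

__all__ = [
    "CorrelationResult",
    "delayed_correlation",
    "pearson_matrix",
    "autocorrelation_curve",
    "decay_time",
    "lag_to_frames",
]


@dataclass
class CorrelationResult:
    """Correlation coefficients, atoms × atoms × lags."""

    lags_ns: np.ndarray
    values: np.ndarray
    mode: str
    labels: list[str]

    def to_csv(self, path: str | Path, lag_index: int = 0) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values[:, :, lag_index], index=self.labels, columns=self.labels
        ).to_csv(path)


def lag_to_frames(tau_ns: float, timestep_ns: float) -> int:
    """Convert a lag in ns to an integer frame count; non-commensurate lags
    are an error rather than silently rounded."""
    m = tau_ns / timestep_ns
    m_int = int(round(m))
    if abs(m - m_int) > 1e-9 * max(1.0, abs(m)):
        raise ValueError(
            f"lag {tau_ns} ns is not an integer multiple of the timestep {timestep_ns} ns"
        )
    if m_int < 0:
        raise ValueError("lag must be non-negative")
    return m_int


def _series(fset: FluctuationSet, i: int, mode: str) -> np.ndarray:
    if mode == "vector":
        return fset.vectors[:, i, :]  # zero-mean by construction
    if mode == "magnitude":
        x = fset.magnitudes[:, i]
        return x - x.mean()
    raise ValueError(f"unknown correlation mode {mode!r}")


def _xcorr(x: np.ndarray, y: np.ndarray, m: int) -> float:
    """Normalized lagged correlation of mean-centred series (1-D scalars or
    frames × 3 vectors); denominators use full-series second moments."""
    n = x.shape[0]
    if m >= n - 1:
        raise ValueError(f"lag of {m} frames leaves fewer than 2 pairs (n={n})")
    vx = np.mean(np.sum(np.atleast_2d(x.reshape(n, -1)) ** 2, axis=1))
    vy = np.mean(np.sum(np.atleast_2d(y.reshape(n, -1)) ** 2, axis=1))
    if vx <= 0 or vy <= 0:
        raise ValueError("zero-variance series in correlation")
    xa = x.reshape(n, -1)[: n - m if m else n]
    ya = y.reshape(n, -1)[m:]
    num = np.sum(xa * ya) / (n - m)
    return float(num / math.sqrt(vx * vy))


def delayed_correlation(
    fset: FluctuationSet, i: int, j: int, tau_ns: float, mode: str = "magnitude"
) -> float:
    """C_ij(τ): correlation of i's fluctuation at t with j's at t+τ.

    Averaged over the n_T − m overlapping frame pairs (m = τ/ξ frames);
    asymmetric in (i, j) for τ > 0, which is what encodes causality.
    """
    m = lag_to_frames(tau_ns, fset.timestep_ns)
    return _xcorr(_series(fset, i, mode), _series(fset, j, mode), m)


def pearson_matrix(fset: FluctuationSet, mode: str = "vector") -> CorrelationResult:
    """Symmetric τ = 0 Pearson correlation map over all atom pairs."""
    n = fset.n_atoms
    if mode == "vector":
        v = fset.vectors
        cov = np.einsum("tia,tja->ij", v, v) / fset.n_frames
    elif mode == "magnitude":
        x = fset.magnitudes - fset.magnitudes.mean(axis=0)
        cov = x.T @ x / fset.n_frames
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"zero-variance atoms at indices {bad.tolist()}")
    denom = np.sqrt(var)
    # symmetrize before normalizing so C_ij == C_ji bit-for-bit
    cov = (cov + cov.T) / 2.0
    values = cov / np.outer(denom, denom)
    return CorrelationResult(
        np.array([0.0]), values[:, :, None], mode, fset.residue_labels
    )


def autocorrelation_curve(
    fset: FluctuationSet,
    i: int,
    lags_ns: Sequence[float],
    mode: str = "magnitude",
) -> np.ndarray:
    """C_ii(τ) over the given lags; equals 1 at τ = 0."""
    x = _series(fset, i, mode)
    return np.array(
        [_xcorr(x, x, lag_to_frames(t, fset.timestep_ns)) for t in lags_ns]
    )


def decay_time(
    curve: Sequence[float],
    timestep_ns: float | None = None,
    lags_ns: Sequence[float] | None = None,
) -> float:
    """First lag where the curve falls to 1/e of its τ = 0 value.

    Linearly interpolates between the bracketing lags; returns ``inf`` when
    the curve never crosses within the sampled range.  Lags are taken as
    uniform multiples of ``timestep_ns`` unless ``lags_ns`` is given.
    """
    curve = np.asarray(curve, dtype=np.float64)
    if curve.size == 0:
        raise ValueError("empty correlation curve")
    if curve[0] <= 0:
        raise ValueError("decay time requires a positive value at zero lag")
    if lags_ns is None:
        if timestep_ns is None:
            raise ValueError("provide timestep_ns or explicit lags_ns")
        lags_ns = np.arange(curve.size) * timestep_ns
    lags_ns = np.asarray(lags_ns, dtype=np.float64)
    target = curve[0] / math.e
    below = np.flatnonzero(curve < target)
    if below.size == 0:
        return math.inf
    k = below[0]
    if k == 0:  # cannot happen for curve[0] > 0, defensive
        return float(lags_ns[0])
    frac = (curve[k - 1] - target) / (curve[k - 1] - curve[k])
    return float(lags_ns[k - 1] + frac * (lags_ns[k] - lags_ns[k - 1]))


def lag_curves_to_csv(
    path: str | Path,
    lags_ns: Sequence[float],
    curves: dict[str, Sequence[float]],
) -> None:
    """Long-format CSV writer: one (label, lag_ns, value) row per point."""
    import pandas as pd

    rows = [
        {"pair": label, "lag_ns": lag, "value": val}
        for label, curve in curves.items()
        for lag, val in zip(lags_ns, curve)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
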