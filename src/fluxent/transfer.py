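"""Schreiber transfer entropy between residue fluctuation series.

The transfer entropy from series i to series j at lag τ,

    T_i→j(τ) = S(j_τ | j_0) − S(j_τ | i_0, j_0)
             = S(j_0, j_τ) − S(i_0, j_0, j_τ) − S(j_0) + S(i_0, j_0),

measures the reduction in uncertainty about j's future state given i's
present state beyond what j's own present provides.  It is estimated from
a single empirical triple histogram over (state_i(t), state_j(t),
state_j(t+τ)) pooled over all overlapping frame pairs (stationarity);
every marginal is derived from that one table, which guarantees

    0 ≤ T_i→j(τ) ≤ S_1,i     and     T_i→j(0) = 0

exactly (up to float round-off).  Net pairwise exchange T_i→j − T_j→i and
the per-residue net transfer Σ_j (T_i→j − T_j→i) classify residues into
entropy sources (positive net) and sinks (negative net).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .entropy import StateSeries, shannon

__all__ = [
    "TransferEntropyResult",
    "TEPair",
    "StateComparison",
    "conditional_entropy",
    "transfer_entropy_pair",
    "te_matrix",
    "classify_sources_sinks",
    "compare_states",
    "te_convergence",
]

_NEG_CLIP = 1e-9  # float round-off scale below zero that is clipped


@dataclass
class TEPair:
    """Transfer entropy of one ordered pair plus occupied-cell counts."""

    te: float
    te_corrected: float
    m_j: int
    m_ij: int
    m_jjt: int
    m_ijjt: int
    n_pairs: int


@dataclass
class TransferEntropyResult:
    """All-pairs transfer entropy at one lag.

    ``te`` is the atoms × atoms matrix T_i→j (row = donor i, column =
    acceptor j; diagonal fixed at 0 and excluded from sums).
    ``net_exchange`` = T_i→j − T_j→i is antisymmetric;
    ``net_per_residue``[i] = Σ_j net_exchange[i, j] sums to 0 over i.
    All values in k_B.
    """

    tau_frames: int
    tau_ns: float
    te: np.ndarray
    net_exchange: np.ndarray
    net_per_residue: np.ndarray
    s1: np.ndarray
    occupied_cells: np.ndarray
    corrected: bool
    labels: list[str] = field(default_factory=list)

    def to_csv(self, outdir: str | Path, prefix: str = "") -> None:
        import pandas as pd

        outdir = Path(outdir)
        labels = self.labels or [str(k + 1) for k in range(len(self.s1))]
        pd.DataFrame(self.te, index=labels, columns=labels).to_csv(
            outdir / f"{prefix}transfer_entropy.csv"
        )
        pd.DataFrame(self.net_exchange, index=labels, columns=labels).to_csv(
            outdir / f"{prefix}net_exchange.csv"
        )
        pd.DataFrame(
            {"residue": labels, "net_transfer_kB": self.net_per_residue}
        ).to_csv(outdir / f"{prefix}net_per_residue.csv", index=False)


def _lagged_states(
    ss: StateSeries, i: int, j: int, tau_frames: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = ss.n_frames
    if not 0 <= tau_frames < n - 1:
        raise ValueError(
            f"lag of {tau_frames} frames leaves fewer than 2 pairs (n={n})"
        )
    stop = n - tau_frames
    return (
        ss.states[:stop, i],
        ss.states[:stop, j],
        ss.states[tau_frames:, j],
    )


def conditional_entropy(ss: StateSeries, i: int, j: int, tau_frames: int) -> float:
    """S(j_τ | i_0) = S(i_0, j_τ) − S(i_0) from the lagged pair histogram."""
    si, _, sjt = _lagged_states(ss, i, j, tau_frames)
    b = ss.n_bins
    joint = np.bincount((si - 1) * b + (sjt - 1), minlength=b * b).reshape(b, b)
    return shannon(joint) - shannon(joint.sum(axis=1))


def transfer_entropy_pair(
    ss: StateSeries, i: int, j: int, tau_frames: int
) -> TEPair:
    """T_i→j(τ) from one empirical triple histogram.

    Returns both the raw plug-in value and a bias-corrected one in which
    each of the four entropy terms receives its own (M − 1)/(2N) finite-
    sample correction; the corrected value may be negative.
    """
    if i == j:
        raise ValueError("transfer entropy is defined for distinct series")
    si, sj0, sjt = _lagged_states(ss, i, j, tau_frames)
    b = ss.n_bins
    flat = ((si - 1) * b + (sj0 - 1)) * b + (sjt - 1)
    triple = np.bincount(flat, minlength=b**3).reshape(b, b, b)
    n_pairs = si.shape[0]

    jjt = triple.sum(axis=0)  # (j_0, j_τ)
    ij = triple.sum(axis=2)  # (i_0, j_0)
    j0 = jjt.sum(axis=1)  # (j_0,)

    te = shannon(jjt) - shannon(triple) - shannon(j0) + shannon(ij)
    if -_NEG_CLIP < te < 0:
        te = 0.0

    m_jjt = int(np.count_nonzero(jjt))
    m_ijjt = int(np.count_nonzero(triple))
    m_ij = int(np.count_nonzero(ij))
    m_j = int(np.count_nonzero(j0))
    correction = (m_jjt - m_ijjt - m_j + m_ij) / (2.0 * n_pairs)
    return TEPair(te, te + correction, m_j, m_ij, m_jjt, m_ijjt, n_pairs)


def te_matrix(
    ss: StateSeries, tau_frames: int, correct: bool = False, tau_ns: float | None = None
) -> TransferEntropyResult:
    """Transfer entropy for every ordered pair, with nets.

    ``correct`` switches the reported matrix to the per-term bias-corrected
    estimates (off by default: corrections can push values slightly below
    zero, breaking the exact bounds of the raw estimator).
    """
    n = ss.n_series
    if n < 2:
        raise ValueError("need at least 2 series")
    te = np.zeros((n, n))
    cells = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pair = transfer_entropy_pair(ss, i, j, tau_frames)
            te[i, j] = pair.te_corrected if correct else pair.te
            cells[i, j] = pair.m_ijjt
    net = te - te.T
    s1 = np.array([shannon(np.bincount(ss.states[:, k])[1:]) for k in range(n)])
    return TransferEntropyResult(
        tau_frames,
        tau_ns if tau_ns is not None else float(tau_frames),
        te,
        net,
        net.sum(axis=1),
        s1,
        cells,
        correct,
        list(ss.labels),
    )


def classify_sources_sinks(
    res: TransferEntropyResult, threshold: float = 0.0
) -> list[str]:
    """Label each residue: net transfer above ``threshold`` is a source,
    below −``threshold`` a sink, otherwise neutral."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    labels = []
    for v in res.net_per_residue:
        if v > threshold:
            labels.append("source")
        elif v < -threshold:
            labels.append("sink")
        else:
            labels.append("neutral")
    return labels


@dataclass
class StateComparison:
    """Per-residue change in net entropy transfer between two states."""

    delta: np.ndarray  # net_bound − net_free
    labels_free: list[str]
    labels_bound: list[str]
    changed: np.ndarray  # bool: classification flipped
    residue_labels: list[str]

    def to_csv(self, path: str | Path, net_free=None, net_bound=None) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "residue": self.residue_labels
                or [str(k + 1) for k in range(len(self.delta))],
                "class_free": self.labels_free,
                "class_bound": self.labels_bound,
                "delta_net_kB": self.delta,
                "changed": self.changed,
            }
        )
        if net_free is not None:
            df.insert(1, "net_free_kB", net_free)
        if net_bound is not None:
            df.insert(2, "net_bound_kB", net_bound)
        df.to_csv(path, index=False)


def compare_states(
    res_free: TransferEntropyResult,
    res_bound: TransferEntropyResult,
    threshold: float = 0.0,
) -> StateComparison:
    """Bound-minus-free change in per-residue net transfer, flagging
    residues whose source/sink/neutral classification flips (e.g. a sink
    in the free state that is no longer a sink once complexed)."""
    if len(res_free.net_per_residue) != len(res_bound.net_per_residue):
        raise ValueError("results cover different residue sets")
    if res_free.labels and res_bound.labels and res_free.labels != res_bound.labels:
        raise ValueError("results cover different residue sets")
    if res_free.tau_frames != res_bound.tau_frames:
        raise ValueError("results computed at different lags")
    lf = classify_sources_sinks(res_free, threshold)
    lb = classify_sources_sinks(res_bound, threshold)
    delta = res_bound.net_per_residue - res_free.net_per_residue
    changed = np.array([a != b for a, b in zip(lf, lb)])
    return StateComparison(delta, lf, lb, changed, list(res_free.labels))


def te_convergence(
    ss: StateSeries,
    tau_frames: int,
    checkpoints: Sequence[int],
    correct: bool = False,
) -> tuple[list[TransferEntropyResult], np.ndarray]:
    """Transfer-entropy matrices on growing data prefixes.

    Returns the per-checkpoint results and max |ΔT| between successive
    checkpoints, a practical convergence diagnostic for trajectory length.
    """
    checkpoints = list(checkpoints)
    if any(b < a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be non-decreasing")
    if checkpoints and checkpoints[-1] > ss.n_frames:
        raise ValueError("checkpoint beyond available frames")
    results = [
        te_matrix(ss.prefix(n), tau_frames, correct=correct) for n in checkpoints
    ]
    deltas = np.array(
        [
            np.abs(b.te - a.te).max()
            for a, b in zip(results, results[1:])
        ]
    )
    return results, deltas
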