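"""Histogram (binned-state) entropy and mutual-information estimation.

Fluctuation magnitudes are discretized into equal-width bins spanning each
atom's own [min, max] range ("adaptive" binning); each bin is a state, and
empirical state frequencies give plug-in Shannon entropies in units of k_B
(natural log, k_B ≡ 1):

    S_1,i   = −Σ_k p_i(k) ln p_i(k)
    S_2,ij  = −Σ_kl p_ij(k,l) ln p_ij(k,l)
    I_2,ij  = S_1,i + S_1,j − S_2,ij   (mutual information, ≥ 0)

Marginals are always re-derived from the joint table, which makes the
identity above exact and keeps the uncorrected mutual information
non-negative and bounded by min(S_1,i, S_1,j).

The default bin count is 8; alternatively a modified Sturges rule,
n_opt = f̄ · (1 + log2 N), scales the classic Sturges count by the mean
normalized fluctuation f̄ of the data.  Finite-sample (Miller–Madow type)
bias corrections are available:

    S_true ≈ S_est + (M − 1)/(2N)
    I_true ≈ I_est + (M_ij − M_i − M_j + 1)/(2N)

with M the number of occupied histogram bins and N the sample count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fluctuation import FluctuationSet

__all__ = [
    "BinningScheme",
    "StateSeries",
    "EntropyReport",
    "PairEntropy",
    "sturges_bins",
    "compute_mean_norm_fluct",
    "discretize",
    "discretize_series",
    "singlet_entropy",
    "pair_entropy_and_mi",
    "correct_singlet",
    "correct_mi",
    "entropy_report",
    "configurational_entropy_change",
    "shannon",
]


# -- binning -----------------------------------------------------------------

@dataclass
class BinningScheme:
    """Equal-width per-series bin edges spanning each series' [min, max]."""

    n_bins: int
    edges: np.ndarray  # (n_series, n_bins + 1)
    degenerate: np.ndarray  # bool per series: min == max (single occupied bin)


@dataclass
class StateSeries:
    """Discretized series: integer bin indices in [1, n_bins] per frame."""

    states: np.ndarray  # (n_T, n_series) int
    scheme: BinningScheme
    labels: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_series(self) -> int:
        return self.states.shape[1]

    @property
    def n_bins(self) -> int:
        return self.scheme.n_bins

    def prefix(self, n_frames: int) -> "StateSeries":
        """First ``n_frames`` frames with the same binning (for convergence
        checks)."""
        return StateSeries(self.states[:n_frames], self.scheme, self.labels)


def sturges_bins(mean_norm_fluct: float, n_samples: int) -> int:
    """Modified Sturges rule: round(f̄ · (1 + log2 N)), at least 2 bins.

    ``mean_norm_fluct`` is the mean fluctuation magnitude divided by the
    maximum (in (0, 1]); ``n_samples`` is the number of frames.
    """
    if not 0 < mean_norm_fluct <= 1:
        raise ValueError("mean_norm_fluct must be in (0, 1]")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    n_opt = int(round(mean_norm_fluct * (1.0 + math.log2(n_samples))))
    return max(2, n_opt)


def compute_mean_norm_fluct(fset: FluctuationSet) -> float:
    """Mean fluctuation magnitude over all atoms and frames divided by the
    global maximum magnitude; in (0, 1]."""
    mags = fset.magnitudes
    mx = mags.max()
    if mx <= 0:
        raise ValueError("all fluctuation magnitudes are zero")
    return float(min(mags.mean() / mx, 1.0))


def discretize_series(
    values: np.ndarray, n_bins: int, labels: Sequence[str] | None = None
) -> StateSeries:
    """Bin each column of ``values`` (frames × series) into ``n_bins``
    equal-width bins over that column's [min, max]; the maximum maps into
    the top bin.  Constant columns are flagged degenerate (all frames in
    bin 1)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be frames × series")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    degenerate = hi <= lo
    span = np.where(degenerate, 1.0, hi - lo)
    raw = np.floor((values - lo[None, :]) / span[None, :] * n_bins).astype(np.int64)
    states = np.clip(raw, 0, n_bins - 1) + 1
    states[:, degenerate] = 1
    edges = lo[:, None] + np.linspace(0.0, 1.0, n_bins + 1)[None, :] * span[:, None]
    return StateSeries(
        states,
        BinningScheme(n_bins, edges, degenerate),
        list(labels) if labels is not None else [],
    )


def discretize(fset: FluctuationSet, n_bins: int = 8) -> StateSeries:
    """Discretize the fluctuation magnitudes of every atom."""
    return discretize_series(fset.magnitudes, n_bins, fset.residue_labels)


# -- entropies ---------------------------------------------------------------

def shannon(counts: np.ndarray) -> float:
    """−Σ p ln p from a (possibly multi-dimensional) count table, in k_B;
    empty bins contribute nothing (0·ln 0 ≡ 0)."""
    c = np.asarray(counts, dtype=np.float64).ravel()
    total = c.sum()
    if total <= 0:
        raise ValueError("empty count table")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log(p)))


def singlet_entropy(ss: StateSeries, i: int) -> float:
    """S_1,i of one series from its occupancy histogram (k_B)."""
    counts = np.bincount(ss.states[:, i], minlength=ss.n_bins + 1)[1:]
    return shannon(counts)


@dataclass
class PairEntropy:
    """Joint entropy, mutual information, and occupied-bin counts of a pair."""

    s2: float
    i2: float
    s1_i: float
    s1_j: float
    m_i: int
    m_j: int
    m_ij: int


def _joint_counts(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray:
    flat = (a - 1) * n_bins + (b - 1)
    return np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)


def pair_entropy_and_mi(ss: StateSeries, i: int, j: int) -> PairEntropy:
    """Joint entropy S_2,ij and mutual information I_2,ij of two series.

    Marginals come from the joint table itself, so S_2 = S_1,i + S_1,j − I_2
    holds exactly and the uncorrected I_2 is ≥ 0.
    """
    if i == j:
        raise ValueError("pair entropy requires two distinct series")
    joint = _joint_counts(ss.states[:, i], ss.states[:, j], ss.n_bins)
    s2 = shannon(joint)
    mi_counts = joint.sum(axis=1)
    mj_counts = joint.sum(axis=0)
    s1_i = shannon(mi_counts)
    s1_j = shannon(mj_counts)
    i2 = s1_i + s1_j - s2
    return PairEntropy(
        s2,
        i2,
        s1_i,
        s1_j,
        int(np.count_nonzero(mi_counts)),
        int(np.count_nonzero(mj_counts)),
        int(np.count_nonzero(joint)),
    )


def correct_singlet(s_est: float, m_occupied: int, n_samples: int) -> float:
    """Finite-sample correction S_true ≈ S_est + (M − 1)/(2N)."""
    if m_occupied < 1 or n_samples < 1:
        raise ValueError("counts must be positive")
    return s_est + (m_occupied - 1) / (2.0 * n_samples)


def correct_mi(
    i_est: float, m_ij: int, m_i: int, m_j: int, n_samples: int
) -> float:
    """Finite-sample correction I_true ≈ I_est + (M_ij − M_i − M_j + 1)/(2N).

    The corrected value may legitimately be negative and is reported as-is.
    """
    if min(m_ij, m_i, m_j, n_samples) < 1:
        raise ValueError("counts must be positive")
    return i_est + (m_ij - m_i - m_j + 1) / (2.0 * n_samples)


# -- whole-system report -----------------------------------------------------

@dataclass
class EntropyReport:
    """Singlet/pair entropies and mutual information over all series.

    ``s1``/``i2`` hold raw plug-in values; when ``corrected`` is set the
    ``s1_corrected``/``i2_corrected`` fields carry the bias-corrected ones.
    """

    s1: np.ndarray  # (n,)
    s2: np.ndarray  # (n, n), 0 on diagonal
    i2: np.ndarray  # (n, n), 0 on diagonal
    m1: np.ndarray  # (n,) occupied bins
    m2: np.ndarray  # (n, n) occupied joint bins
    n_samples: int
    corrected: bool
    s1_corrected: np.ndarray | None = None
    i2_corrected: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def total(self) -> float:
        """Pairwise-truncated configurational entropy Σ_i S1_i − Σ_{i<j} I2_ij
        (corrected values when available), in k_B."""
        s1 = self.s1_corrected if self.corrected else self.s1
        i2 = self.i2_corrected if self.corrected else self.i2
        n = len(s1)
        iu = np.triu_indices(n, k=1)
        return float(s1.sum() - i2[iu].sum())


def entropy_report(ss: StateSeries, correct: bool = True) -> EntropyReport:
    """Compute S1 for every series and S2/I2 for every pair."""
    n = ss.n_series
    s1 = np.zeros(n)
    m1 = np.zeros(n, dtype=int)
    s2 = np.zeros((n, n))
    i2 = np.zeros((n, n))
    m2 = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts = np.bincount(ss.states[:, i], minlength=ss.n_bins + 1)[1:]
        s1[i] = shannon(counts)
        m1[i] = int(np.count_nonzero(counts))
    for i in range(n):
        for j in range(i + 1, n):
            pe = pair_entropy_and_mi(ss, i, j)
            s2[i, j] = s2[j, i] = pe.s2
            i2[i, j] = i2[j, i] = pe.i2
            m2[i, j] = m2[j, i] = pe.m_ij
    report = EntropyReport(
        s1, s2, i2, m1, m2, ss.n_frames, correct, labels=list(ss.labels)
    )
    if correct:
        report.s1_corrected = np.array(
            [correct_singlet(s1[i], m1[i], ss.n_frames) for i in range(n)]
        )
        i2c = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                i2c[i, j] = i2c[j, i] = correct_mi(
                    i2[i, j], m2[i, j], m1[i], m1[j], ss.n_frames
                )
        report.i2_corrected = i2c
    return report


def configurational_entropy_change(
    report_bound: EntropyReport, report_free: EntropyReport
) -> float:
    """ΔS (k_B) between two states of the same system:
    [Σ S1 − Σ_{i<j} I2]_bound − [same]_free."""
    if len(report_bound.s1) != len(report_free.s1):
        raise ValueError("entropy reports cover different atom sets")
    if report_bound.labels and report_free.labels:
        if report_bound.labels != report_free.labels:
            raise ValueError("entropy reports cover different atom sets")
    return report_bound.total() - report_free.total()
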