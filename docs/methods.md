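# Methods

## Model and procedure

fluxent quantifies directional communication between protein residues from
equilibrium fluctuation trajectories. The chain of operations is:

1. **Alignment.** Every frame is superposed onto a reference frame by the
   least-squares (Kabsch) rigid-body fit over a fit selection (default:
   alpha carbons), removing global rotation and translation. The rotation
   is obtained from `scipy.spatial.transform.Rotation.align_vectors`, a
   deterministic closed-form solution. Analysis atoms and fit atoms are
   independently selectable.
2. **Fluctuations.** After an explicit equilibration trim (a frame count
   chosen by the user, never auto-detected, for reproducibility), each
   atom's time-mean position R̄_i is subtracted, giving fluctuation vectors
   ΔR_i(t) and magnitudes |ΔR_i(t)|. Mean positions are computed after
   trimming. The mean-square fluctuation relates to the B-factor through
   B = (8π²/3)⟨ΔR²⟩.
3. **Correlations.** The time-delayed cross-correlation
   C_ij(τ) = ⟨ΔR_i(t)·ΔR_j(t+τ)⟩ / (⟨ΔR_i²⟩⟨ΔR_j²⟩)^½ is estimated over
   all n_T − τ/ξ overlapping frame pairs, with denominators from the
   full-series second moments. Two modes exist because the two downstream
   uses want different series: `vector` mode (3-D dot products of the
   mean-centred fluctuation vectors) produces the familiar dynamic
   cross-correlation map with genuine negative correlations down to −1;
   `magnitude` mode (mean-centred scalar magnitudes) matches the series
   used for entropy estimation. A driver residue is diagnosed by its
   forward curve C_ij(τ) decaying more slowly than the reverse curve
   C_ji(τ); decay times are read off at the 1/e crossing with linear
   interpolation between bracketing lags (an `inf` sentinel when the curve
   never crosses in range).
4. **Discretization.** Magnitudes are binned per atom into equal-width
   bins spanning that atom's own [min, max] (the maximum falls in the top
   bin); each bin is a state. The default bin count is 8; `--bins auto`
   applies a modified Sturges rule n_opt = round(f̄·(1 + log₂ N)) with f̄
   the mean magnitude divided by the global maximum and N the frame count.
   At f̄ = 0.4 and N = 600,000 this gives 8, the operating point used
   throughout. Nearest-integer rounding is used (floor agrees at that
   operating point); the floor of 2 bins keeps degenerate inputs usable.
   Pair and triple histograms reuse each atom's 1-D edges rather than
   re-adapting in higher dimensions.
5. **Entropies.** Plug-in Shannon entropies with natural log, in units of
   k_B (k_B ≡ 1): S₁ per atom, joint S₂ and mutual information I₂ per
   pair. All marginals are re-derived from the joint table; this makes
   S₂ = S₁ᵢ + S₁ⱼ − I₂ exact, keeps the uncorrected I₂ ≥ 0, and enforces
   I₂ ≤ min(S₁ᵢ, S₁ⱼ). Empty bins contribute nothing (0·ln 0 ≡ 0).
6. **Finite-sample corrections.** Miller–Madow-type first-order
   corrections S_true ≈ S_est + (M−1)/(2N) and
   I_true ≈ I_est + (M_ij − M_i − M_j + 1)/(2N), with M the occupied-bin
   counts. Corrected mutual information may legitimately be negative and
   is reported as-is. The correction removes the leading (mean) bias; it
   does not and cannot reduce per-replicate sampling scatter, and for
   concentrated distributions with many near-empty cells the first-order
   term removes only part of the total bias (observed: roughly 70–75% for
   8³-cell triple histograms at N = 10⁵).
7. **Transfer entropy.** Schreiber's measure at lag τ,
   T_i→j(τ) = S(j₀, j_τ) − S(i₀, j₀, j_τ) − S(j₀) + S(i₀, j₀),
   estimated from a single empirical triple histogram over
   (state_i(t), state_j(t), state_j(t+τ)) with all four terms derived from
   that one table. This consistency guarantees 0 ≤ T_i→j ≤ S₁ᵢ,
   −S₁ⱼ ≤ T_i→j − T_j→i ≤ S₁ᵢ, and T_i→j(0) = 0 exactly (float round-off
   below 1e-9 is clipped to zero). Estimation pools all overlapping frame
   pairs from a single origin under stationarity; a per-term bias
   correction ΔT = (M_jjτ − M_ijjτ − M_j + M_ij)/(2N′) is available but
   off by default, since corrected values can fall slightly below zero.
8. **Nets and profiles.** Pairwise net exchange T_i→j − T_j→i
   (antisymmetric), per-residue net transfer Σ_j (T_i→j − T_j→i) (sums to
   zero over residues by construction), source/sink classification by a
   sign rule with a user threshold, and bound-minus-free comparison with
   flags for residues whose classification flips upon complex formation.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `timestep_ns` ξ | ns | from file / required flag | converts lags between ns and frames; non-commensurate lags are an error, never rounded |
| `n_skip` | frames | 0 | equilibration trim; explicit for reproducibility |
| `bins` | count | 8 | the Sturges operating point for long trajectories; `auto` recomputes it from the data |
| `tau_ns` | ns | 5 | sits inside the 1–10 ns correlation-decay window where the T_i→j vs T_j→i asymmetry is largest; at τ→0 TE vanishes identically, at τ ≫ decay time it vanishes through decorrelation |
| `correct` | flag | on for S₁/I₂, off for TE | see items 6–7 |
| `threshold` | k_B | 0 (classification), 0.0035 (landscape display floor) | the display floor only masks small values in the reported landscape table; it is never applied to computation |

## Synthetic data

The generator produces stationary VAR(1) series x(t+1) = A·x(t) + ε(t)
with spectral radius ρ(A) < 1, innovation SD 1 by default, and a burn-in
of 10 autocorrelation times (−1/ln ρ frames). The causal ground truth is
the sparsity pattern of A, so driver/driven claims have an unambiguous
reference. For Gaussian VAR(1) the transfer entropy has the closed form
½·ln[Var(x_j(t+τ)|x_j(t)) / Var(x_j(t+τ)|x_j(t), x_i(t))] computed from
the exact stationary covariance (discrete Lyapunov equation); this is the
independent oracle against which the histogram estimator is checked
(8-bin discretization biases the estimate low by roughly 20% at coupling
0.5 — the documented binning bias inside the 25% agreement band).

`make_protein_fixture` embeds such series in a toy alpha-carbon chain:
residue k at (3.8k, 0, 0) Å, displaced each frame by (|z_k(t)| + 0.1) Å
along a random direction, so the fluctuation magnitude tracks |z_k(t)|
while the empirical mean stays at the base position. What this emulates:
stationary, exponentially correlated, directionally coupled fluctuation
magnitudes — the statistical features the estimators consume. What it
does not: anharmonic multi-well dynamics, slow conformational switching,
sidechain coupling, or solvent memory. Passing tests therefore validate
the estimators, not any claim about a specific protein; residue-level
results for real systems require real MD input.

Test and acceptance problem sizes (10⁴–2·10⁵ frames, 2–5 series,
100-seed ensembles) were chosen so each statistical check resolves its
effect a few times above its own noise floor.

## Numerical choices and degenerate inputs

- Histogram state indices are 1-based; bin assignment is
  floor((x−min)/width) clipped into the top bin, so the maximum always
  maps to bin n_bins.
- Constant (zero-range) series are flagged degenerate and occupy bin 1;
  zero-variance series are an error for correlations (undefined) but fine
  for entropies (S₁ = 0).
- Pearson maps symmetrize the covariance before normalizing so the matrix
  equals its transpose bit-for-bit.
- The columnar text trajectory dialect writes %.17g, which round-trips
  float64 exactly.
- Mean normalized fluctuation is clamped at 1.0 against float round-up
  when all magnitudes are equal.

## Known limitations

- Histogram TE at 8 bins underestimates the continuous-variable value
  (binning bias); comparisons across systems at fixed binning remain
  valid, absolute values should not be read as continuous TE.
- First-order bias corrections leave residual bias when many cells hold
  O(1) counts; TE significance should rest on the provided null bands,
  not on corrected point values alone.
- Only pairwise (single-conditioning) transfer entropy is implemented; no
  multi-residue conditioning, no surrogate-based significance testing
  beyond the null-band checks, no sidechain analysis.
- Magnitude-based entropies discard the direction of motion; anti-phase
  and in-phase coupling of equal strength are indistinguishable to the
  entropy pipeline (the vector-mode Pearson map is the place to see the
  sign).
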