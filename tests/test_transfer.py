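import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxent as fx

from oracles import conditional_entropy_of, entropy_of, transfer_entropy_of


def _state_series(states, n_bins=None, labels=()):
    states = np.asarray(states)
    b = n_bins or max(int(states.max()), 2)
    return fx.StateSeries(
        states,
        fx.BinningScheme(b, np.zeros((states.shape[1], b + 1)), np.zeros(states.shape[1], bool)),
        list(labels),
    )


state_arrays = st.integers(2, 5).flatmap(
    lambda b: st.lists(
        st.tuples(st.integers(1, b), st.integers(1, b)), min_size=8, max_size=150
    )
)


class TestConditionalEntropy:
    def test_deterministic_shift_gives_zero(self, rng):
        x = rng.integers(1, 5, 2000)
        y = np.empty_like(x)
        y[2:] = x[:-2]
        y[:2] = 1
        ss = _state_series(np.column_stack([x, y]))
        # y(t+2) is exactly x(t): no residual uncertainty
        assert fx.conditional_entropy(ss, 0, 1, 2) == pytest.approx(0.0, abs=1e-9)

    def test_independent_series_approach_marginal_entropy(self, rng):
        states = rng.integers(1, 5, size=(100_000, 2))
        ss = _state_series(states)
        s1_j = fx.singlet_entropy(ss, 1)
        cond = fx.conditional_entropy(ss, 0, 1, 3)
        assert cond == pytest.approx(s1_j, abs=5e-4)
        assert cond <= s1_j + 1e-12  # conditioning never increases entropy

    def test_six_frame_hand_enumeration(self):
        x = [1, 2, 1, 2, 1, 2]
        y = [1, 1, 2, 2, 1, 1]
        ss = _state_series(np.column_stack([x, y]))
        expected = conditional_entropy_of(x, y, 1)
        assert fx.conditional_entropy(ss, 0, 1, 1) == pytest.approx(
            expected, abs=1e-12
        )

    def test_excessive_lag_rejected(self, rng):
        ss = _state_series(rng.integers(1, 3, (10, 2)))
        with pytest.raises(ValueError):
            fx.conditional_entropy(ss, 0, 1, 9)


class TestTransferEntropyPair:
    def test_zero_lag_vanishes_exactly(self, rng):
        ss = _state_series(rng.integers(1, 9, (500, 2)))
        assert fx.transfer_entropy_pair(ss, 0, 1, 0).te == 0.0
        assert fx.transfer_entropy_pair(ss, 1, 0, 0).te == 0.0

    def test_independent_series_within_bias_scale(self, rng):
        ss = _state_series(rng.integers(1, 9, (100_000, 2)))
        pair = fx.transfer_entropy_pair(ss, 0, 1, 1)
        bias = (pair.m_ijjt + pair.m_j - pair.m_jjt - pair.m_ij) / (
            2 * pair.n_pairs
        )
        assert 0 <= pair.te <= 3 * bias

    def test_binary_copy_process_transfers_ln2(self, rng):
        n = 200_000
        x = rng.integers(1, 3, n)
        y = np.empty_like(x)
        y[1:] = x[:-1]
        y[0] = 1
        ss = _state_series(np.column_stack([x, y]))
        fwd = fx.transfer_entropy_pair(ss, 0, 1, 1).te
        rev = fx.transfer_entropy_pair(ss, 1, 0, 1).te
        assert fwd == pytest.approx(math.log(2), abs=1e-3)
        assert rev == pytest.approx(0.0, abs=1e-3)

    def test_matches_brute_force_enumeration(self, rng):
        states = rng.integers(1, 5, size=(600, 2))
        ss = _state_series(states)
        for tau in [1, 3]:
            expected = transfer_entropy_of(
                list(states[:, 0]), list(states[:, 1]), tau
            )
            assert fx.transfer_entropy_pair(ss, 0, 1, tau).te == pytest.approx(
                expected, abs=1e-12
            )

    def test_gaussian_var1_close_to_analytic(self):
        model = fx.Var1Model(
            np.array([[0.5, 0.0], [0.5, 0.5]]), 1.0, 100_000, seed=21
        )
        x = fx.simulate_var1(model)
        ss = fx.discretize_series(x, 8)
        est = fx.transfer_entropy_pair(ss, 0, 1, 1).te
        exact = fx.analytic_gaussian_te(model, 0, 1, 1)
        assert abs(est - exact) / exact < 0.25

    def test_same_series_rejected(self, rng):
        ss = _state_series(rng.integers(1, 3, (50, 2)))
        with pytest.raises(ValueError):
            fx.transfer_entropy_pair(ss, 0, 0, 1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(state_arrays, st.integers(0, 3))
    def test_bounds_hold_for_any_series(self, pairs, tau):
        states = np.array(pairs)
        if tau >= states.shape[0] - 1:
            tau = 0
        ss = _state_series(states)
        s1_i = entropy_of(list(states[:, 0]))
        s1_j = entropy_of(list(states[:, 1]))
        fwd = fx.transfer_entropy_pair(ss, 0, 1, tau).te
        rev = fx.transfer_entropy_pair(ss, 1, 0, tau).te
        assert 0 <= fwd <= s1_i + 1e-9
        assert -s1_j - 1e-9 <= fwd - rev <= s1_i + 1e-9


class TestTeMatrix:
    def test_independent_series_nets_within_null_band(self, rng):
        ss = _state_series(rng.integers(1, 9, (20_000, 3)))
        res = fx.te_matrix(ss, 1)
        # all uncorrected TEs are pure bias here; nets cancel to near zero
        assert np.abs(res.net_exchange).max() < 0.01

    def test_driven_chain_classifies_source_and_sink(self):
        a = np.array([[0.5, 0, 0], [0.6, 0.5, 0], [0, 0, 0.5]])
        model = fx.Var1Model(a, 1.0, 50_000, seed=9)
        x = fx.simulate_var1(model)
        res = fx.te_matrix(fx.discretize_series(x, 8), 1)
        net = res.net_per_residue
        assert net[0] > 0  # driver
        assert net[1] < 0  # driven
        assert abs(net[2]) < min(net[0], -net[1])  # bystander

    def test_net_transfer_sums_to_zero(self, rng):
        ss = _state_series(rng.integers(1, 6, (3000, 4)))
        res = fx.te_matrix(ss, 2)
        assert np.allclose(res.net_exchange, -res.net_exchange.T)
        assert res.net_per_residue.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(res.te) == 0)

    def test_te_bounded_by_donor_entropy(self, rng):
        ss = _state_series(rng.integers(1, 6, (2000, 3)))
        res = fx.te_matrix(ss, 1)
        for i in range(3):
            assert np.all(res.te[i, :] <= res.s1[i] + 1e-9)

    def test_single_series_rejected(self, rng):
        ss = _state_series(rng.integers(1, 3, (50, 1)))
        with pytest.raises(ValueError):
            fx.te_matrix(ss, 1)


class TestClassification:
    def _result(self, nets):
        nets = np.asarray(nets, dtype=float)
        n = len(nets)
        return fx.TransferEntropyResult(
            1, 1.0, np.zeros((n, n)), np.zeros((n, n)), nets,
            np.ones(n), np.zeros((n, n), dtype=int), False,
            [f"ALA{k+1}" for k in range(n)],
        )

    def test_sign_rule(self):
        res = self._result([0.5, -0.5, 0.001])
        assert fx.classify_sources_sinks(res, 0.01) == ["source", "sink", "neutral"]

    def test_zero_threshold_leaves_no_neutrals_except_exact_zero(self):
        res = self._result([0.2, -0.3, 0.0])
        assert fx.classify_sources_sinks(res, 0.0) == ["source", "sink", "neutral"]

    def test_all_zero_nets_are_neutral(self):
        res = self._result([0.0, 0.0])
        assert fx.classify_sources_sinks(res, 0.0) == ["neutral", "neutral"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            fx.classify_sources_sinks(self._result([0.1]), -1.0)


class TestCompareStates:
    def _res_from_states(self, states, tau=1):
        return fx.te_matrix(_state_series(states, n_bins=8), tau)

    def test_identical_results_give_zero_delta(self, rng):
        states = rng.integers(1, 9, (3000, 3))
        res = self._res_from_states(states)
        cmp = fx.compare_states(res, res)
        assert np.all(cmp.delta == 0)
        assert not cmp.changed.any()

    def test_swapped_inputs_negate_delta(self, rng):
        a = self._res_from_states(rng.integers(1, 9, (3000, 3)))
        b = self._res_from_states(rng.integers(1, 9, (3000, 3)))
        assert np.allclose(
            fx.compare_states(a, b).delta, -fx.compare_states(b, a).delta
        )

    def test_removed_coupling_flags_driver(self):
        coupled = np.array([[0.5, 0.0], [0.6, 0.5]])
        free_model = fx.Var1Model(coupled, 1.0, 50_000, seed=3)
        bound_model = fx.Var1Model(np.eye(2) * 0.5, 1.0, 50_000, seed=4)
        res_free = fx.te_matrix(
            fx.discretize_series(fx.simulate_var1(free_model), 8), 1
        )
        res_bound = fx.te_matrix(
            fx.discretize_series(fx.simulate_var1(bound_model), 8), 1
        )
        cmp = fx.compare_states(res_free, res_bound, threshold=0.002)
        assert cmp.labels_free[0] == "source"
        assert cmp.labels_bound[0] == "neutral"
        assert cmp.changed[0]

    def test_lag_mismatch_rejected(self, rng):
        states = rng.integers(1, 9, (3000, 3))
        with pytest.raises(ValueError):
            fx.compare_states(
                self._res_from_states(states, tau=1),
                self._res_from_states(states, tau=2),
            )

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fx.compare_states(
                self._res_from_states(rng.integers(1, 9, (1000, 3))),
                self._res_from_states(rng.integers(1, 9, (1000, 2))),
            )


class TestConvergence:
    def test_final_checkpoint_equals_full_matrix(self, rng):
        states = rng.integers(1, 6, (4000, 3))
        ss = _state_series(states)
        results, deltas = fx.te_convergence(ss, 1, [1000, 2000, 4000])
        full = fx.te_matrix(ss, 1)
        assert np.array_equal(results[-1].te, full.te)
        assert deltas.shape == (2,)

    def test_equal_checkpoints_give_zero_delta(self, rng):
        ss = _state_series(rng.integers(1, 6, (2000, 2)))
        _, deltas = fx.te_convergence(ss, 1, [1500, 1500])
        assert deltas[0] == 0.0

    def test_stationary_process_converges(self):
        model = fx.Var1Model(
            np.array([[0.5, 0.0], [0.5, 0.5]]), 1.0, 60_000, seed=13
        )
        ss = fx.discretize_series(fx.simulate_var1(model), 8)
        _, deltas = fx.te_convergence(ss, 1, [2000, 10_000, 60_000])
        assert deltas[-1] < deltas[0]

    def test_checkpoint_beyond_data_rejected(self, rng):
        ss = _state_series(rng.integers(1, 4, (100, 2)))
        with pytest.raises(ValueError):
            fx.te_convergence(ss, 1, [50, 200])
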