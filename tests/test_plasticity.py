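"""Reward, RL update, transfer kernel and STDP consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from songlearn import (
    KernelMismatchError,
    NetworkParams,
    NetworkState,
    TrialRecord,
    compute_kernel,
    compute_reward,
    identity_kernel,
    make_hvc_code,
    rl_update,
    stdp_update,
    weight_correlation,
)
from songlearn.stimuli import HVCCode

from conftest import random_state


def code_from_matrix(matrix: np.ndarray) -> HVCCode:
    return HVCCode(
        matrix=np.asarray(matrix, dtype=float),
        onsets=np.zeros(matrix.shape[0], dtype=int),
        decay_const=20.0,
    )


def make_trial(n_ra, n_hvc, T, rng, reward=None):
    return TrialRecord(
        x_activity=rng.normal(size=(n_ra, T)),
        l_activity=rng.normal(size=(n_ra, T)),
        ra_activity=rng.normal(size=(n_ra, T)),
        motor_out=rng.normal(size=(2, T)),
        eligibility=rng.normal(size=(n_ra, n_hvc)),
        noise_eligibility=rng.normal(size=(n_ra, n_hvc)),
        reward=reward,
    )


class TestComputeReward:
    def test_perfect_imitation_scores_one(self, small_template):
        assert compute_reward(small_template.traces.copy(), small_template) == 1.0
        assert compute_reward(small_template.traces.copy(), small_template,
                              normalized=True) == 1.0

    def test_normalized_hand_example(self):
        # template all 0.5, silent output, T=2: 1 - (4 * 0.5)/4 = 0.5
        template = np.full((2, 2), 0.5)
        assert compute_reward(np.zeros((2, 2)), template, normalized=True) == 0.5

    def test_raw_sum_hand_example(self):
        # same traces, unnormalized: 1 - 4*0.5 = -1
        template = np.full((2, 2), 0.5)
        assert compute_reward(np.zeros((2, 2)), template) == -1.0

    def test_invariant_under_joint_time_permutation(self, rng):
        m = rng.uniform(0, 1, (2, 11))
        mhat = rng.uniform(0, 1, (2, 11))
        perm = rng.permutation(11)
        assert compute_reward(mhat, m) == pytest.approx(
            compute_reward(mhat[:, perm], m[:, perm]), rel=1e-14
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_reward(np.zeros((2, 3)), np.zeros((2, 4)))


class TestRLUpdate:
    def _state(self, m, params):
        return NetworkState(
            m_weights=np.array(m, dtype=float),
            w_weights=np.zeros_like(np.asarray(m, dtype=float)),
            a_readout=np.zeros((2, np.asarray(m).shape[0])),
            reward_baseline=0.0,
        )

    def test_zero_gradient_and_no_decay_leaves_weights(self, rng):
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4, tau_m_decay=1e15)
        state = self._state([[1.0, 2.0], [3.0, 4.0]], params)
        state.reward_baseline = 0.7
        trial = make_trial(2, 2, 4, rng, reward=0.7)  # reward == baseline
        before = state.m_weights.copy()
        rl_update(state, trial, params)
        np.testing.assert_allclose(state.m_weights, before, rtol=1e-12)

    def test_zero_learning_rate_is_pure_decay(self, rng):
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4, eta_rl=0.0,
                               tau_m_decay=100.0)
        state = self._state([[1.0, -2.0], [0.5, 4.0]], params)
        trial = make_trial(2, 2, 4, rng, reward=0.9)
        before = state.m_weights.copy()
        rl_update(state, trial, params)
        np.testing.assert_allclose(state.m_weights, before * (1 - 1 / 100.0),
                                   rtol=1e-12)

    def test_update_matches_elementwise_oracle(self):
        """2x2 instance against an independent scalar-by-scalar evaluation."""
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4, eta_rl=1e-3,
                               tau_m_decay=1e6, eligibility_form="lman")
        m0 = np.array([[0.3, -0.1], [0.2, 0.5]])
        state = self._state(m0, params)
        state.reward_baseline = 0.4
        elig = np.array([[1.0, 0.0], [0.0, 1.0]])
        trial = TrialRecord(
            x_activity=np.zeros((2, 4)), l_activity=np.zeros((2, 4)),
            ra_activity=np.zeros((2, 4)), motor_out=np.zeros((2, 4)),
            eligibility=elig, reward=0.5,
        )
        rl_update(state, trial, params)
        expected = np.empty((2, 2))
        for i in range(2):  # brute-force scalar oracle
            for j in range(2):
                step = m0[i, j] + 1e-3 * elig[i, j] * (0.5 - 0.4)
                expected[i, j] = step - step / 1e6
        np.testing.assert_allclose(state.m_weights, expected, rtol=1e-13)

    def test_baseline_moves_as_exponential_average(self, rng):
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4, baseline_alpha=0.1)
        state = self._state([[1.0, 0.0], [0.0, 1.0]], params)
        state.reward_baseline = 0.2
        trial = make_trial(2, 2, 4, rng, reward=1.2)
        rl_update(state, trial, params)
        assert state.reward_baseline == pytest.approx(0.9 * 0.2 + 0.1 * 1.2)

    def test_first_trial_initializes_baseline_to_its_reward(self, rng):
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4)
        state = self._state([[1.0, 0.0], [0.0, 1.0]], params)
        state.reward_baseline = None
        before = state.m_weights.copy()
        trial = make_trial(2, 2, 4, rng, reward=0.33)
        rl_update(state, trial, params)
        # gradient term vanished (R - Rbar = 0); only decay applied
        np.testing.assert_allclose(state.m_weights, before * (1 - 1e-6), rtol=1e-12)
        assert state.reward_baseline == pytest.approx(0.33)

    def test_linear_in_learning_rate(self, rng):
        base = NetworkParams(n_hvc=3, n_ra=2, n_steps=4, tau_m_decay=1e15)
        halved = NetworkParams(n_hvc=3, n_ra=2, n_steps=4, tau_m_decay=1e15,
                               eta_rl=base.eta_rl / 2)
        trial = make_trial(2, 3, 4, rng, reward=0.8)
        m0 = np.zeros((2, 3))  # zero start so the decay term is identically zero
        s1 = NetworkState(m_weights=m0.copy(), w_weights=np.zeros((2, 3)),
                          a_readout=np.zeros((2, 2)), reward_baseline=0.1)
        s2 = NetworkState(m_weights=m0.copy(), w_weights=np.zeros((2, 3)),
                          a_readout=np.zeros((2, 2)), reward_baseline=0.1)
        rl_update(s1, trial, base)
        rl_update(s2, trial, halved)
        np.testing.assert_allclose(s2.m_weights - m0, (s1.m_weights - m0) / 2,
                                   rtol=1e-12)

    def test_missing_reward_rejected(self, rng):
        params = NetworkParams(n_hvc=2, n_ra=2, n_steps=4)
        state = self._state([[1.0, 0.0], [0.0, 1.0]], params)
        with pytest.raises(ValueError, match="reward"):
            rl_update(state, make_trial(2, 2, 4, rng, reward=None), params)


class TestComputeKernel:
    def test_identity_code_gives_identity_kernel(self):
        code = code_from_matrix(np.eye(6))
        kernel = compute_kernel(code)
        np.testing.assert_allclose(kernel.k_matrix, np.eye(6), atol=1e-12)

    def test_scaled_identity_code(self):
        # (2I) K (2I) = I forces K = I/4
        code = code_from_matrix(2 * np.eye(5))
        kernel = compute_kernel(code)
        np.testing.assert_allclose(kernel.k_matrix, np.eye(5) / 4, atol=1e-12)

    def test_full_row_rank_wide_code_gives_exact_identity(self, rng):
        H = rng.normal(size=(5, 8))
        kernel = compute_kernel(code_from_matrix(H))
        np.testing.assert_allclose(H @ kernel.k_matrix @ H.T, np.eye(5),
                                   atol=1e-8)

    def test_paper_geometry_gives_rank_t_projector(self):
        code = make_hvc_code(160, 80)
        kernel = compute_kernel(code)
        P = code.matrix @ kernel.k_matrix @ code.matrix.T
        np.testing.assert_allclose(P, P.T, atol=1e-8)
        np.testing.assert_allclose(P @ P, P, atol=1e-8)
        assert np.linalg.matrix_rank(P, tol=1e-6) == 80
        assert kernel.projector_residual < 1e-6

    def test_kernel_is_symmetric(self, rng):
        kernel = compute_kernel(code_from_matrix(rng.normal(size=(7, 9))))
        np.testing.assert_allclose(kernel.k_matrix, kernel.k_matrix.T, atol=1e-8)

    def test_rank_deficient_code_warns_not_fails(self):
        H = np.zeros((4, 6))
        H[0] = H[1] = np.linspace(1, 2, 6)  # rank 1
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            kernel = compute_kernel(code_from_matrix(H))
        assert np.isfinite(kernel.projector_residual)

    @given(n=st.integers(2, 6), t=st.integers(2, 9), seed=st.integers(0, 99))
    @settings(max_examples=40, deadline=None)
    def test_projector_property_for_any_code(self, n, t, seed):
        """H K H^T is always a symmetric idempotent (an orthogonal projector)."""
        H = np.random.default_rng(seed).normal(size=(n, t))
        kernel = compute_kernel(code_from_matrix(H))
        P = H @ kernel.k_matrix @ H.T
        np.testing.assert_allclose(P, P.T, atol=1e-8)
        np.testing.assert_allclose(P @ P, P, atol=1e-8)


class TestSTDPUpdate:
    def test_zero_rate_is_pure_decay(self, rng):
        params = NetworkParams(n_hvc=3, n_ra=2, n_steps=3, eta_stdp=0.0,
                               tau_w_decay=50.0)
        code = code_from_matrix(rng.normal(size=(3, 3)))
        kernel = compute_kernel(code)
        w0 = rng.normal(size=(2, 3))
        state = NetworkState(m_weights=np.zeros((2, 3)), w_weights=w0.copy(),
                             a_readout=np.zeros((2, 2)))
        trial = make_trial(2, 3, 3, rng, reward=0.5)
        stdp_update(state, trial, kernel, code, params)
        np.testing.assert_allclose(state.w_weights, w0 * (1 - 1 / 50.0), rtol=1e-12)

    def test_idealized_transfer_is_proportional_to_m(self, rng):
        """With post = M H, full row rank H (N <= T) and no decay, a single
        update changes W by a multiple of M exactly."""
        n_hvc, n_ra, T = 4, 3, 7
        params = NetworkParams(n_hvc=n_hvc, n_ra=n_ra, n_steps=T,
                               tau_w_decay=1e15, stdp_post="x")
        H = rng.normal(size=(n_hvc, T))
        code = code_from_matrix(H)
        kernel = compute_kernel(code)
        m = rng.normal(size=(n_ra, n_hvc))
        state = NetworkState(m_weights=m, w_weights=np.zeros((n_ra, n_hvc)),
                             a_readout=np.zeros((2, n_ra)))
        trial = make_trial(n_ra, n_hvc, T, rng, reward=0.5)
        trial.x_activity = m @ H  # the idealized postsynaptic activity
        stdp_update(state, trial, kernel, code, params, post="x")
        delta = state.w_weights
        np.testing.assert_allclose(delta, params.eta_stdp * m, atol=1e-10)
        assert weight_correlation(delta, m) == pytest.approx(1.0, abs=1e-8)

    def test_matches_triple_product_oracle(self, rng):
        """2-neuron instance against a brute-force matrix-product evaluation."""
        n_hvc, n_ra, T = 2, 2, 3
        params = NetworkParams(n_hvc=n_hvc, n_ra=n_ra, n_steps=T,
                               eta_stdp=1e-4, tau_w_decay=1e5, stdp_post="ra")
        H = np.array([[1.0, 0.5, 0.2], [0.0, 1.0, 0.4]])
        code = code_from_matrix(H)
        kernel = compute_kernel(code)
        w0 = np.array([[0.1, -0.2], [0.3, 0.4]])
        state = NetworkState(m_weights=np.zeros((2, 2)), w_weights=w0.copy(),
                             a_readout=np.zeros((2, 2)))
        trial = make_trial(n_ra, n_hvc, T, rng, reward=0.8)
        # independent oracle: elementwise triple product, then decay
        hebb = np.zeros((2, 2))
        for i in range(n_ra):
            for j in range(n_hvc):
                for t1 in range(T):
                    for t2 in range(T):
                        hebb[i, j] += (trial.ra_activity[i, t1]
                                       * kernel.k_matrix[t1, t2] * H[j, t2])
        expected = w0 + 1e-4 * hebb
        expected -= expected / 1e5
        stdp_update(state, trial, kernel, code, params, post="ra")
        np.testing.assert_allclose(state.w_weights, expected, rtol=1e-12)

    def test_stale_kernel_rejected(self, rng):
        params = NetworkParams(n_hvc=3, n_ra=2, n_steps=3)
        code = code_from_matrix(rng.normal(size=(3, 3)))
        other = code_from_matrix(rng.normal(size=(3, 3)))
        kernel = compute_kernel(other)
        state = NetworkState(m_weights=np.zeros((2, 3)),
                             w_weights=np.zeros((2, 3)),
                             a_readout=np.zeros((2, 2)))
        with pytest.raises(KernelMismatchError):
            stdp_update(state, make_trial(2, 3, 3, rng, reward=0.5),
                        kernel, code, params)

    def test_identity_kernel_is_identity_matrix(self, small_code):
        kernel = identity_kernel(small_code)
        np.testing.assert_array_equal(kernel.k_matrix, np.eye(small_code.n_steps))
        assert kernel.source_code_hash == small_code.digest

    def test_linear_in_learning_rate(self, rng):
        n_hvc, n_ra, T = 3, 2, 4
        H = rng.normal(size=(n_hvc, T))
        code = code_from_matrix(H)
        kernel = compute_kernel(code)
        trial = make_trial(n_ra, n_hvc, T, rng, reward=0.6)
        deltas = []
        for eta in (2e-4, 1e-4):
            params = NetworkParams(n_hvc=n_hvc, n_ra=n_ra, n_steps=T,
                                   eta_stdp=eta, tau_w_decay=1e15)
            state = NetworkState(m_weights=np.zeros((n_ra, n_hvc)),
                                 w_weights=np.zeros((n_ra, n_hvc)),
                                 a_readout=np.zeros((2, n_ra)))
            stdp_update(state, trial, kernel, code, params)
            deltas.append(state.w_weights.copy())
        np.testing.assert_allclose(deltas[0], 2 * deltas[1], rtol=1e-12)


class TestWeightCorrelation:
    def test_self_correlation_is_one(self, rng):
        w = rng.normal(size=(4, 5))
        assert weight_correlation(w, w) == pytest.approx(1.0)
        assert weight_correlation(w, -w) == pytest.approx(-1.0)

    def test_matches_two_pass_pearson_oracle(self, rng):
        w = rng.normal(size=(6, 7))
        m = rng.normal(size=(6, 7))
        a, b = w.ravel(), m.ravel()
        da, db = a - a.mean(), b - b.mean()  # independent two-pass formula
        expected = (da @ db) / np.sqrt((da @ da) * (db @ db))
        assert weight_correlation(w, m) == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            weight_correlation(np.ones((3, 3)), rng.normal(size=(3, 3)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            weight_correlation(np.ones((2, 3)), np.ones((3, 2)))


class TestDecayOnlyContraction:
    def test_weights_contract_geometrically_without_learning(self, rng):
        """eta = 0 for both rules: per-iteration factors (1 - 1/tau_M), (1 - 1/tau_W)."""
        n_hvc, n_ra, T = 3, 2, 4
        params = NetworkParams(n_hvc=n_hvc, n_ra=n_ra, n_steps=T,
                               eta_rl=0.0, eta_stdp=0.0,
                               tau_m_decay=200.0, tau_w_decay=40.0)
        code = code_from_matrix(rng.normal(size=(n_hvc, T)))
        kernel = compute_kernel(code)
        m0 = rng.normal(size=(n_ra, n_hvc))
        w0 = rng.normal(size=(n_ra, n_hvc))
        state = NetworkState(m_weights=m0.copy(), w_weights=w0.copy(),
                             a_readout=np.zeros((2, n_ra)), reward_baseline=0.0)
        n_rounds = 7
        for _ in range(n_rounds):
            trial = make_trial(n_ra, n_hvc, T, rng, reward=0.5)
            rl_update(state, trial, params)
            stdp_update(state, trial, kernel, code, params)
        np.testing.assert_allclose(state.m_weights, m0 * (1 - 1 / 200.0) ** n_rounds,
                                   rtol=1e-12)
        np.testing.assert_allclose(state.w_weights, w0 * (1 - 1 / 40.0) ** n_rounds,
                                   rtol=1e-12)
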