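import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import softmax

from astw.astw import (
    AttentionConfig,
    attention_fuse,
    astw_step,
    extract_features,
    fuse_stream,
    init_state,
    softmax_weights,
    stw_step,
)
from astw.errors import ConfigError, ContractError
from astw.io_preprocess import segment_windows

vec9 = st.lists(st.floats(0, 50), min_size=9, max_size=9)


class TestAttention:
    def test_zero_current_features_give_zero_output(self, rng):
        prev = rng.standard_normal(30)
        out = attention_fuse(np.zeros(30), prev)
        np.testing.assert_array_equal(out, np.zeros(30))

    @given(curr=vec9, prev=vec9)
    def test_softmax_rows_sum_to_one(self, curr, prev):
        W = softmax_weights(np.array(curr), np.array(prev))
        np.testing.assert_allclose(W.sum(axis=1), np.ones(3), atol=1e-12)

    def test_hand_example_three_by_one(self):
        """curr = prev = (1,2,3) as a 3x1 matrix, d_k = 1.

        Scores are rows (1,2,3), (2,4,6), (3,6,9); expected output frozen
        from an independent row-softmax computation (scipy.special.softmax).
        """
        v = np.array([1.0, 2.0, 3.0])
        out = attention_fuse(v, v, AttentionConfig(d_k=1.0))
        Q = v.reshape(3, 1)
        oracle = (softmax(Q @ Q.T, axis=1) @ Q).ravel()
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        np.testing.assert_allclose(out, [2.575210, 2.850937, 2.947975], atol=1e-4)
        assert out[0] == pytest.approx(2.5752, abs=1e-4)

    @given(curr=vec9, prev=vec9)
    def test_output_rows_are_convex_combinations(self, curr, prev):
        curr, prev = np.array(curr), np.array(prev)
        out = attention_fuse(curr, prev).reshape(3, 3)
        Q = curr.reshape(3, 3)
        lo, hi = Q.min(axis=0), Q.max(axis=0)
        assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_length_not_divisible_by_three_rejected(self):
        with pytest.raises(ContractError):
            attention_fuse(np.zeros(4), np.zeros(4))


class TestCellState:
    def test_zero_cell_passes_input_through(self, rng):
        x = rng.standard_normal(6)
        f, state = stw_step(x, init_state(6))
        np.testing.assert_array_equal(f, x)
        np.testing.assert_array_equal(state.c, x)
        assert state.t == 1

    def test_beta_zero_disables_memory(self, rng):
        state = init_state(6, beta=0.0)
        state.c = rng.standard_normal(6)
        x = rng.standard_normal(6)
        f, _ = stw_step(x, state)
        np.testing.assert_array_equal(f, x)

    def test_constant_input_converges_to_geometric_limit(self):
        """f_t -> v / (1 - beta) = 4 v for beta = 0.75 on constant input."""
        v = np.full(5, 2.0)
        state = init_state(5, beta=0.75)
        for _ in range(20):
            f, state = stw_step(v, state)
        np.testing.assert_allclose(f, 4 * v, rtol=0.01)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ConfigError):
            init_state(3, beta=1.0)


class TestAstwStep:
    def test_first_window_uses_self_attention(self, rng):
        x = np.abs(rng.standard_normal(30))
        f, _ = astw_step(x, None, init_state(30))
        np.testing.assert_allclose(f, attention_fuse(x, x))

    def test_beta_zero_gives_pure_attention_stream(self, rng):
        rows = np.abs(rng.standard_normal((6, 30)))
        out = fuse_stream(rows, mode="astw", beta=0.0)
        prev = rows[0]
        for t in range(6):
            expected = attention_fuse(rows[t], prev if t else rows[0])
            np.testing.assert_allclose(out[t], expected)
            prev = rows[t]

    def test_zero_stream_is_fixed_point(self):
        out = fuse_stream(np.zeros((7, 12)), mode="astw")
        np.testing.assert_array_equal(out, np.zeros((7, 12)))

    @given(rows=st.lists(vec9, min_size=2, max_size=8), beta=st.floats(0, 0.9))
    def test_bounded_memory(self, rows, beta):
        rows = np.array(rows)
        M = np.abs(rows).max()
        out = fuse_stream(rows, mode="astw", beta=beta)
        assert np.abs(out).max() <= M / (1 - beta) + 1e-6


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "condition,length", [("emg", 30), ("emg+acc", 84), ("merged", 39)]
    )
    def test_row_lengths_by_condition(self, tiny_trial, condition, length):
        stream = segment_windows(tiny_trial, 150.0)
        F, y = extract_features(stream, condition=condition)
        assert F.shape == (len(stream), length)
        assert y.shape == (len(stream),)

    def test_one_row_per_window(self, tiny_trial):
        stream = segment_windows(tiny_trial, 100.0)
        F, y = extract_features(stream, condition="emg")
        assert F.shape[0] == len(stream) == y.shape[0]

    def test_trial_order_does_not_change_per_trial_features(self, tiny_cfg):
        from astw.synthetic_data import generate_trial

        trials = [generate_trial(tiny_cfg, 0, t) for t in range(2)]
        feats = {}
        for order in ((0, 1), (1, 0)):
            for t in order:
                stream = segment_windows(trials[t], 150.0)
                F, _ = extract_features(stream, condition="emg")
                feats.setdefault(t, []).append(F)
        for t in (0, 1):
            np.testing.assert_array_equal(feats[t][0], feats[t][1])

    def test_missing_acc_channels_rejected(self, tiny_trial):
        stream = segment_windows(tiny_trial, 150.0)
        emg_only = type(stream)(
            windows=stream.windows[:, :, stream.emg_indices],
            wl_ms=stream.wl_ms,
            stride_ms=stream.stride_ms,
            labels=stream.labels,
            channel_roles=("EMG",) * 5,
        )
        with pytest.raises(ConfigError):
            extract_features(emg_only, condition="emg+acc")
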