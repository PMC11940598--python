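"""Building-block math: activations, LSTM cell vs a scalar oracle,
bidirectional wrapper, multi-scale convolution, attention."""

import math

import numpy as np
import pytest

from eegfuse.nn.functional import (
    AttentionTensors,
    LSTMCellParams,
    LSTMState,
    bilstm_layer,
    conv1d_same,
    dot_product_attention,
    leaky_relu,
    lstm_cell_step,
    multiscale_conv_block,
    relu,
    standardize,
)


@pytest.mark.parametrize("x,expected", [(-5.0, 0.0), (3.0, 3.0), (0.0, 0.0)])
def test_relu_branches(x, expected):
    assert relu(np.array(x)) == expected


@pytest.mark.parametrize("x,a,expected", [(-2.0, 0.1, -0.2), (4.0, 0.1, 4.0)])
def test_leaky_relu_branches(x, a, expected):
    assert leaky_relu(np.array(x), a) == pytest.approx(expected)


def test_leaky_relu_zero_slope_reduces_to_relu(rng):
    x = rng.normal(size=100)
    assert np.array_equal(leaky_relu(x, 0.0), relu(x))


# ---------------------------------------------------------------------------
# LSTM cell vs scalar oracle


def scalar_lstm_oracle(x, h_prev, c_prev, p: LSTMCellParams):
    """Element-by-element evaluation of the gate recurrences with plain
    Python floats — independent of the array implementation."""
    H, Ix = p.hidden_size, p.input_size

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def affine(w_i, b_i, w_h, b_h, row):
        s = b_i[row] + b_h[row]
        for j in range(Ix):
            s += w_i[row][j] * x[j]
        for j in range(H):
            s += w_h[row][j] * h_prev[j]
        return s

    h_out, c_out = [], []
    for r in range(H):
        f = sig(affine(p.w_if, p.b_if, p.w_hf, p.b_hf, r))
        i = sig(affine(p.w_ii, p.b_ii, p.w_hi, p.b_hi, r))
        g = math.tanh(affine(p.w_ig, p.b_ig, p.w_hg, p.b_hg, r))
        o = sig(affine(p.w_io, p.b_io, p.w_ho, p.b_ho, r))
        c = f * c_prev[r] + i * g
        h_out.append(o * math.tanh(c))
        c_out.append(c)
    return np.array(h_out), np.array(c_out)


def test_lstm_zero_params_zero_cell():
    p = LSTMCellParams.zeros(3, 2)
    st = lstm_cell_step(np.zeros(2), LSTMState.zeros(3), p)
    assert np.allclose(st.c, 0) and np.allclose(st.h, 0)


def test_lstm_zero_params_nonzero_cell_hand_value():
    """With all weights zero, every gate is 0.5 and g=0, so c_prev=2
    halves to c=1 and h = 0.5*tanh(1)."""
    p = LSTMCellParams.zeros(1, 1)
    st = lstm_cell_step(np.zeros(1), LSTMState(np.zeros(1), np.array([2.0])), p)
    assert st.c[0] == pytest.approx(1.0, abs=1e-12)
    assert st.h[0] == pytest.approx(0.5 * math.tanh(1.0), abs=1e-9)
    assert st.h[0] == pytest.approx(0.380797, abs=1e-6)


def test_lstm_cell_matches_scalar_oracle_randomized(rng):
    for _ in range(100):
        H = int(rng.integers(1, 5))
        Ix = int(rng.integers(1, 5))
        p = LSTMCellParams.random(H, Ix, rng)
        x = rng.normal(size=Ix)
        prev = LSTMState(rng.normal(size=H), rng.normal(size=H))
        got = lstm_cell_step(x, prev, p)
        h_ref, c_ref = scalar_lstm_oracle(x, prev.h, prev.c, p)
        np.testing.assert_allclose(got.h, h_ref, atol=1e-6)
        np.testing.assert_allclose(got.c, c_ref, atol=1e-6)


def test_lstm_shape_mismatch_names_tensor():
    p = LSTMCellParams.zeros(2, 3)
    with pytest.raises(ValueError, match="x_t"):
        lstm_cell_step(np.zeros(4), LSTMState.zeros(2), p)
    with pytest.raises(ValueError, match="prev.h"):
        lstm_cell_step(np.zeros(3), LSTMState.zeros(5), p)


class TestBiLSTMLayer:
    def test_single_step_symmetry(self, rng):
        fwd = LSTMCellParams.random(3, 2, rng)
        bwd = LSTMCellParams.random(3, 2, rng)
        seq = rng.normal(size=(1, 2))
        out = bilstm_layer(seq, fwd, bwd)
        exp_f = lstm_cell_step(seq[0], LSTMState.zeros(3), fwd).h
        exp_b = lstm_cell_step(seq[0], LSTMState.zeros(3), bwd).h
        np.testing.assert_allclose(out[0, :3], exp_f)
        np.testing.assert_allclose(out[0, 3:], exp_b)

    def test_palindrome_with_tied_params(self, rng):
        """On a palindromic sequence with bwd params = fwd params, the
        reversed output equals the output with halves swapped."""
        p = LSTMCellParams.random(2, 3, rng)
        half = rng.normal(size=(4, 3))
        seq = np.concatenate([half, half[::-1]], axis=0)
        out = bilstm_layer(seq, p, p)
        swapped = np.concatenate([out[:, 2:], out[:, :2]], axis=1)
        np.testing.assert_allclose(out[::-1], swapped, atol=1e-10)

    def test_output_shape_contract(self, rng):
        out = bilstm_layer(rng.normal(size=(7, 4)),
                           LSTMCellParams.random(5, 4, rng),
                           LSTMCellParams.random(5, 4, rng))
        assert out.shape == (7, 10)

    def test_empty_sequence_rejected(self, rng):
        p = LSTMCellParams.random(2, 3, rng)
        with pytest.raises(ValueError):
            bilstm_layer(np.empty((0, 3)), p, p)


# ---------------------------------------------------------------------------
# Convolution


class TestMultiscaleConv:
    def test_1x1_identity_kernel_is_positionwise_linear(self, rng):
        seq = rng.normal(size=(6, 3))
        w = np.eye(3)[None]  # (1, 3, 3) identity
        out = multiscale_conv_block(seq, [w], [np.zeros(3)], activation="relu")
        np.testing.assert_allclose(out, np.maximum(seq, 0))

    def test_two_scales_feature_dim(self, rng):
        seq = rng.normal(size=(10, 5))
        w1 = rng.normal(size=(1, 5, 32))
        w3 = rng.normal(size=(3, 5, 32))
        out = multiscale_conv_block(seq, [w1, w3], [np.zeros(32)] * 2)
        assert out.shape == (10, 64)

    def test_constant_input_constant_interior(self, rng):
        seq = np.full((12, 4), 2.5)
        w = rng.normal(size=(3, 4, 6))
        w -= w.mean(axis=(0, 1), keepdims=True)  # zero-mean kernels
        out = conv1d_same(seq, w, np.zeros(6))
        interior = out[1:-1]
        np.testing.assert_allclose(
            interior, np.broadcast_to(interior[0], interior.shape), rtol=0, atol=1e-10
        )

    def test_sequence_shorter_than_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="kernel"):
            conv1d_same(rng.normal(size=(2, 3)), rng.normal(size=(5, 3, 1)), np.zeros(1))


# ---------------------------------------------------------------------------
# Attention


class TestAttention:
    def test_identical_keys_give_uniform_weights(self, rng):
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        V = rng.normal(size=(5, 3))
        t = AttentionTensors(Q=rng.normal(size=(2, 4)), K=K, V=V, d_k=4)
        out, w = dot_product_attention(t, return_weights=True)
        np.testing.assert_allclose(w, 1 / 5, atol=1e-12)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_hand_computed_softmax_example(self):
        """Q=[1,0] against orthonormal keys: weights softmax(1/sqrt(2), 0)."""
        t = AttentionTensors(Q=[[1.0, 0.0]], K=[[1.0, 0.0], [0.0, 1.0]],
                             V=[[1.0, 0.0], [0.0, 1.0]], d_k=2)
        out, w = dot_product_attention(t, return_weights=True)
        expected = 1.0 / (1.0 + math.exp(-1.0 / math.sqrt(2.0)))
        np.testing.assert_allclose(w, [[expected, 1 - expected]], atol=1e-9)
        np.testing.assert_allclose(out, [[expected, 1 - expected]], atol=1e-9)
        assert w[0, 0] == pytest.approx(0.6698, abs=1e-3)

    def test_rows_are_probability_distributions(self, rng):
        for _ in range(20):
            n, m, dk, dv = rng.integers(1, 6, size=4)
            t = AttentionTensors(Q=rng.normal(size=(n, dk)),
                                 K=rng.normal(size=(m, dk)),
                                 V=rng.normal(size=(m, dv)), d_k=int(dk))
            _, w = dot_product_attention(t, return_weights=True)
            assert (w >= 0).all()
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_weights_invariant_under_shared_rotation(self, rng):
        """Rotating Q and K by the same orthogonal map leaves Q K^T, and
        hence the weights, unchanged."""
        from scipy.stats import ortho_group

        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        V = rng.normal(size=(5, 2))
        R = ortho_group.rvs(4, random_state=0)
        _, w1 = dot_product_attention(AttentionTensors(Q, K, V, 4), return_weights=True)
        _, w2 = dot_product_attention(AttentionTensors(Q @ R, K @ R, V, 4),
                                      return_weights=True)
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionTensors(Q=np.zeros((2, 3)), K=np.zeros((4, 2)),
                             V=np.zeros((4, 2)), d_k=3)
        with pytest.raises(ValueError):
            AttentionTensors(Q=np.zeros((2, 3)), K=np.zeros((4, 3)),
                             V=np.zeros((5, 2)), d_k=3)


# ---------------------------------------------------------------------------
# Normalization


class TestStandardize:
    def test_constant_channel_maps_to_zero(self):
        x = np.full((1, 10, 2), 3.7)
        np.testing.assert_allclose(standardize(x), 0.0)

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=(3, 50, 4))
        once = standardize(x)
        np.testing.assert_allclose(standardize(once), once, atol=1e-6)

    def test_one_two_three_channel(self):
        out = standardize(np.array([[[1.0], [2.0], [3.0]]]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-6)
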