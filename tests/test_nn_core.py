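"""Forward primitives against independently coded brute-force oracles."""

import numpy as np
import pytest

from pulseguard.errors import EmptyInputError, ShapeError
from pulseguard.nn_core import (ConvSpec, LSTMParams, LSTMState,
                                ResidualBlock, conv1d, conv2d, dense,
                                load_lstm_params, lstm_cell, lstm_sequence,
                                max_pool, relu, residual_apply,
                                save_lstm_params, softmax)

# ---------------------------------------------------------------------------
# brute-force oracles (scalar loops, no vectorized shortcuts)
# ---------------------------------------------------------------------------


def conv2d_oracle(m, kernel, stride=1, padding=0):
    m = np.pad(np.asarray(m, float), padding)
    ki, kj = kernel.shape
    rows = m.shape[0] - ki + 1
    cols = m.shape[1] - kj + 1
    out = np.zeros((rows, cols))
    for x in range(rows):
        for y in range(cols):
            acc = 0.0
            for i in range(ki):
                for j in range(kj):
                    acc += m[x + i, y + j] * kernel[i, j]
            out[x, y] = acc
    return out[::stride, ::stride]


def max_pool_oracle(m, window=2):
    m = np.asarray(m, float)
    out = np.zeros((m.shape[0] // window, m.shape[1] // window))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            best = -np.inf
            for a in range(window):
                for b in range(window):
                    best = max(best, m[i * window + a, j * window + b])
            out[i, j] = best
    return out


def lstm_cell_oracle(x, c_prev, h_prev, params):
    """Scalar-loop recurrence, independent of the vectorized implementation."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    hsize = len(h_prev)
    z = list(h_prev) + list(x)
    c_new, h_new = np.zeros(hsize), np.zeros(hsize)
    w_c = params.W_i if params.tie_candidate_to_input_gate else params.W_c
    b_c = params.b_i if params.tie_candidate_to_input_gate else params.b_c
    for u in range(hsize):
        i_u = sig(sum(params.W_i[u][v] * z[v] for v in range(len(z))) + params.b_i[u])
        g_u = np.tanh(sum(w_c[u][v] * z[v] for v in range(len(z))) + b_c[u])
        f_u = sig(sum(params.W_f[u][v] * z[v] for v in range(len(z))) + params.b_f[u])
        o_u = sig(sum(params.W_o[u][v] * z[v] for v in range(len(z))) + params.b_o[u])
        c_new[u] = f_u * c_prev[u] + i_u * g_u
        h_new[u] = o_u * np.tanh(c_new[u])
    return c_new, h_new


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

class TestConv2d:
    def test_hand_computed_identity_diagonal(self):
        out = conv2d([[1, 2], [3, 4]], ConvSpec(kernel=[[1, 0], [0, 1]]))
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(5.0)

    def test_identity_kernel_returns_input(self, rng):
        m = rng.standard_normal((5, 7))
        np.testing.assert_array_equal(conv2d(m, ConvSpec(kernel=[[1.0]])), m)

    @pytest.mark.parametrize("stride,padding", [(1, 0), (2, 0), (1, 1), (2, 2)])
    def test_matches_quadruple_loop_oracle(self, rng, stride, padding):
        for _ in range(25):
            m = rng.standard_normal((6, 6))
            k = rng.standard_normal((3, 3))
            got = conv2d(m, ConvSpec(kernel=k, stride=stride, padding=padding))
            want = conv2d_oracle(m, k, stride=stride, padding=padding)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_kernel_larger_than_input_raises(self):
        with pytest.raises(ShapeError):
            conv2d(np.ones((2, 2)), ConvSpec(kernel=np.ones((3, 3))))

    def test_conv1d_matches_loop(self, rng):
        x = rng.standard_normal(20)
        k = rng.standard_normal(4)
        want = [sum(x[i + j] * k[j] for j in range(4)) for i in range(17)]
        np.testing.assert_allclose(conv1d(x, ConvSpec(kernel=k)), want,
                                   atol=1e-12)


class TestReluAndPool:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_relu_threshold(self, x, expected):
        assert relu(x) == expected

    def test_single_window_max(self):
        np.testing.assert_array_equal(max_pool([[1, 2], [3, 4]]), [[4.0]])

    def test_constant_matrix_halves_dims(self):
        out = max_pool(np.full((6, 8), 3.7))
        assert out.shape == (3, 4)
        assert np.all(out == 3.7)

    def test_matches_windowed_max_oracle(self, rng):
        for _ in range(100):
            m = rng.standard_normal((4, 4))
            np.testing.assert_array_equal(max_pool(m), max_pool_oracle(m))

    def test_one_dimensional_variant(self):
        np.testing.assert_array_equal(max_pool([1.0, 5.0, 2.0, 3.0], window=2),
                                      [5.0, 3.0])

    def test_empty_input_raises(self):
        with pytest.raises(ShapeError):
            max_pool(np.empty((0, 0)))


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

class TestLSTMCell:
    def test_zero_params_zero_state_is_fixed_point(self):
        params = LSTMParams.zeros(2, 3)
        out = lstm_cell(np.ones(2), LSTMState.zeros(3), params)
        np.testing.assert_array_equal(out.C, np.zeros(3))
        np.testing.assert_array_equal(out.h, np.zeros(3))

    def test_zero_params_unit_cell_state_scalar(self):
        # gates all 0.5, candidate 0: C' = 0.5, h' = 0.5 tanh(0.5)
        params = LSTMParams.zeros(1, 1)
        out = lstm_cell(np.array([7.0]), LSTMState(C=[1.0], h=[0.0]), params)
        assert out.C[0] == pytest.approx(0.5, abs=1e-15)
        assert out.h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-12)
        assert out.h[0] == pytest.approx(0.231059, abs=1e-6)

    @pytest.mark.parametrize("tie", [False, True])
    def test_matches_scalar_loop_oracle(self, rng, tie):
        for _ in range(50):
            params = LSTMParams.random(4, 3, rng,
                                       tie_candidate_to_input_gate=tie)
            # random() leaves biases zero; randomize them for a sharper check
            for name in ("b_i", "b_c", "b_f", "b_o"):
                setattr(params, name, rng.standard_normal(3))
            x = rng.standard_normal(4)
            prev = LSTMState(C=rng.standard_normal(3),
                             h=rng.standard_normal(3))
            got = lstm_cell(x, prev, params)
            want_c, want_h = lstm_cell_oracle(x, prev.C, prev.h, params)
            np.testing.assert_allclose(got.C, want_c, atol=1e-10)
            np.testing.assert_allclose(got.h, want_h, atol=1e-10)

    def test_gate_outputs_bounded(self, rng):
        params = LSTMParams.random(2, 5, rng)
        state = lstm_cell(rng.standard_normal(2) * 10,
                          LSTMState.zeros(5), params)
        assert np.all(np.abs(state.h) < 1.0)  # |o| < 1 and |tanh| < 1

    def test_shape_mismatch_names_parameter(self):
        params = LSTMParams.zeros(2, 3)
        with pytest.raises(ShapeError, match="x_p"):
            lstm_cell(np.ones(5), LSTMState.zeros(3), params)


class TestLSTMSequence:
    def test_single_step_equals_cell(self, rng):
        params = LSTMParams.random(2, 3, rng)
        x = rng.standard_normal(2)
        init = LSTMState.zeros(3)
        seq = lstm_sequence([x], init, params)
        cell = lstm_cell(x, init, params)
        assert len(seq) == 1
        np.testing.assert_array_equal(seq[0].C, cell.C)

    def test_zero_params_zero_init_stays_zero(self):
        params = LSTMParams.zeros(1, 2)
        states = lstm_sequence([np.ones(1)] * 5, LSTMState.zeros(2), params)
        for s in states:
            np.testing.assert_array_equal(s.C, np.zeros(2))

    @pytest.mark.parametrize("t_steps", [1, 5, 30])
    def test_geometric_decay_of_unit_cell_state(self, t_steps):
        # zero weights: every forget gate is 0.5, so C_T = 0.5^T
        params = LSTMParams.zeros(1, 1)
        states = lstm_sequence([np.zeros(1)] * t_steps,
                               LSTMState(C=[1.0], h=[0.0]), params)
        assert states[-1].C[0] == pytest.approx(0.5 ** t_steps, abs=1e-12)

    def test_empty_sequence_raises(self):
        with pytest.raises(EmptyInputError):
            lstm_sequence([], LSTMState.zeros(1), LSTMParams.zeros(1, 1))


# ---------------------------------------------------------------------------
# residual / softmax / dense
# ---------------------------------------------------------------------------

class TestResidual:
    def test_zero_inner_is_identity(self, rng):
        x = rng.standard_normal(6)
        block = ResidualBlock(inner=lambda v: np.zeros_like(v))
        np.testing.assert_array_equal(residual_apply(x, block), x)

    def test_identity_inner_doubles(self, rng):
        x = rng.standard_normal(4)
        np.testing.assert_allclose(
            residual_apply(x, ResidualBlock(inner=lambda v: v)), 2 * x)

    def test_random_linear_inner_matches_direct_sum(self, rng):
        for _ in range(100):
            a = rng.standard_normal((5, 5))
            x = rng.standard_normal(5)
            got = residual_apply(x, ResidualBlock(inner=lambda v: a @ v))
            np.testing.assert_allclose(got, a @ x + x, atol=1e-12)

    def test_projection_reconciles_shapes(self, rng):
        p = rng.standard_normal((3, 5))
        x = rng.standard_normal(5)
        got = residual_apply(x, ResidualBlock(inner=lambda v: p @ v,
                                              projection=p))
        np.testing.assert_allclose(got, 2 * p @ x)

    def test_shape_mismatch_without_projection_raises(self):
        block = ResidualBlock(inner=lambda v: v[:2])
        with pytest.raises(ShapeError):
            residual_apply(np.ones(4), block)


class TestSoftmaxDense:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_log_two_case(self):
        np.testing.assert_allclose(softmax([np.log(2), 0.0]),
                                   [2 / 3, 1 / 3], atol=1e-12)

    def test_shift_invariance_and_simplex(self, rng):
        for _ in range(100):
            x = rng.standard_normal(6) * 50
            p = softmax(x)
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(softmax(x + 123.4), p, atol=1e-12)

    def test_dense_identity(self, rng):
        x = rng.standard_normal(4)
        np.testing.assert_array_equal(
            dense(x, np.eye(4), np.zeros(4), "linear"), x)

    def test_dense_scalar_case(self):
        assert dense([3.0], [[2.0]], [1.0], "linear")[0] == pytest.approx(7.0)

    def test_dense_matches_matvec_oracle(self, rng):
        for _ in range(100):
            w = rng.standard_normal((3, 5))
            x = rng.standard_normal(5)
            b = rng.standard_normal(3)
            want = [sum(w[i, j] * x[j] for j in range(5)) + b[i]
                    for i in range(3)]
            np.testing.assert_allclose(dense(x, w, b), want, atol=1e-12)

    def test_dense_shape_error(self):
        with pytest.raises(ShapeError):
            dense(np.ones(3), np.ones((2, 4)), np.zeros(2))


class TestSerialization:
    def test_lstm_params_roundtrip(self, rng, tmp_path):
        params = LSTMParams.random(3, 4, rng, tie_candidate_to_input_gate=True)
        path = tmp_path / "params.h5"
        save_lstm_params(params, path)
        back = load_lstm_params(path)
        np.testing.assert_array_equal(back.W_f, params.W_f)
        np.testing.assert_array_equal(back.b_o, params.b_o)
        assert back.tie_candidate_to_input_gate is True
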