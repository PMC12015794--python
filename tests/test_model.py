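"""Reference cells, engine equivalence, gradients, and training behavior."""

import math

import numpy as np
import pytest

import mannerkit as mk
from mannerkit.errors import ValidationError
from mannerkit.model import (
    LSTMCellParams,
    LSTMState,
    LSTMNetwork,
    NetworkConfig,
    binary_cross_entropy,
    lstm_cell_step,
    rnn_cell_step,
    run_lstm_sequence,
    train,
)
from mannerkit.model.network import _LSTMLayer


def random_cell(rng, hidden, inputs, scale=0.5):
    def w():
        return rng.normal(0, scale, (hidden, hidden + inputs))

    def b():
        return rng.normal(0, scale, hidden)

    return LSTMCellParams(w(), b(), w(), b(), w(), b(), w(), b())


class TestRnnCell:
    def test_zero_weights_give_zero(self):
        a, y = rnn_cell_step(
            np.zeros(3), np.zeros(2), np.zeros((2, 5)), np.zeros(2),
            np.zeros((1, 2)), np.zeros(1),
        )
        assert not a.any() and not y.any()

    def test_scalar_hand_arithmetic(self):
        # a = tanh(0.5*a_prev - 0.3*x + 0.1), y = tanh(0.7*a - 0.2)
        a, y = rnn_cell_step(
            np.array([0.4]), np.array([0.2]),
            np.array([[0.5, -0.3]]), np.array([0.1]),
            np.array([[0.7]]), np.array([-0.2]),
        )
        expected_a = math.tanh(0.5 * 0.2 - 0.3 * 0.4 + 0.1)
        assert a[0] == pytest.approx(expected_a, abs=1e-12)
        assert y[0] == pytest.approx(math.tanh(0.7 * expected_a - 0.2), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError):
            rnn_cell_step(np.zeros(4), np.zeros(2), np.zeros((2, 5)),
                          np.zeros(2), np.zeros((1, 2)), np.zeros(1))


class TestLstmCell:
    def test_zero_weights_zero_state(self):
        params = LSTMCellParams.zeros(3, 2)
        out = lstm_cell_step(np.zeros(2), LSTMState.zeros(3), params)
        # gates are sigmoid(0) = 0.5, candidate tanh(0) = 0 -> state stays 0
        assert not out.c.any() and not out.a.any()

    def test_scalar_hand_arithmetic_both_modes(self):
        params = LSTMCellParams.zeros(1, 1)
        state = LSTMState(np.zeros(1), np.ones(1))
        std = lstm_cell_step(np.zeros(1), state, params, mode="standard")
        strict = lstm_cell_step(np.zeros(1), state, params, mode="strict_paper")
        # c = 0.5*0 + 0.5*1 = 0.5
        assert std.c[0] == pytest.approx(0.5, abs=1e-12)
        assert std.a[0] == pytest.approx(0.5 * math.tanh(0.5), abs=1e-12)
        assert strict.a[0] == pytest.approx(0.25, abs=1e-12)

    def test_modes_agree_for_tiny_cell_state(self):
        rng = np.random.default_rng(3)
        params = random_cell(rng, 4, 3)
        # scale candidate path down so |c| stays < 1e-3
        params = LSTMCellParams(
            params.w_update, params.b_update,
            params.w_forget, params.b_forget,
            params.w_output, params.b_output,
            params.w_candidate * 1e-3, params.b_candidate * 1e-3,
        )
        x = rng.normal(0, 1e-3, 3)
        std = lstm_cell_step(x, LSTMState.zeros(4), params, mode="standard")
        strict = lstm_cell_step(x, LSTMState.zeros(4), params, mode="strict_paper")
        assert np.abs(std.c).max() < 1e-3
        np.testing.assert_allclose(std.a, strict.a, atol=1e-6)

    def test_unknown_mode_and_shape_errors(self):
        params = LSTMCellParams.zeros(2, 2)
        with pytest.raises(ValidationError):
            lstm_cell_step(np.zeros(2), LSTMState.zeros(2), params, mode="keras")
        with pytest.raises(ValidationError):
            lstm_cell_step(np.zeros(5), LSTMState.zeros(2), params)


class TestEngineEquivalence:
    def test_reference_matches_engine_on_100_draws(self):
        """The per-gate reference cell and the vectorized fused-gate engine
        cell agree within 1e-5 on 100 seeded random parameter draws."""
        rng = np.random.default_rng(1234)
        worst = 0.0
        for _ in range(100):
            hidden = int(rng.integers(1, 8))
            inputs = int(rng.integers(1, 8))
            T = int(rng.integers(1, 6))
            layer = _LSTMLayer(inputs, hidden, rng)
            layer.W = rng.normal(0, 0.6, layer.W.shape)
            layer.b = rng.normal(0, 0.6, layer.b.shape)
            xs = rng.normal(0, 1, (T, inputs))
            hs_engine, _ = layer.forward(xs[None])
            hs_ref = run_lstm_sequence(xs, layer.cell_params(), mode="standard")
            worst = max(worst, np.abs(hs_engine[0] - hs_ref).max())
        assert worst < 1e-5

    def test_numerical_gradient_check(self):
        cfg = NetworkConfig(units=(3, 4, 3), dropout_rate=0.1, batch_size=2,
                            epochs=1, seed=7)
        net = LSTMNetwork(cfg, input_size=5, timesteps=4)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 4, 5))
        Y = rng.integers(0, 2, size=(2, 2)).astype(float)

        def loss():
            probs, ctx = net._forward_batch(
                X, training=True, rng=np.random.default_rng(3))
            return binary_cross_entropy(probs, Y), ctx

        _, ctx = loss()
        grads = net._backward_batch(ctx, Y)
        eps = 1e-6
        rel_errors = []
        for p, g in zip(net.params, grads):
            flat_idx = list(np.ndindex(*p.shape))
            for ix in flat_idx[:: max(1, len(flat_idx) // 15)]:
                orig = p[ix]
                p[ix] = orig + eps
                lp, _ = loss()
                p[ix] = orig - eps
                lm, _ = loss()
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                rel_errors.append(
                    abs(num - g[ix]) / max(1e-8, abs(num) + abs(g[ix]))
                )
        assert max(rel_errors) < 1e-3


class TestForward:
    def test_output_shape_and_range(self):
        net = LSTMNetwork(NetworkConfig(units=(4, 4, 4), seed=1))
        probs = net.forward(np.random.default_rng(0).random((15, 60)))
        assert probs.shape == (2,)
        assert ((probs > 0) & (probs < 1)).all()

    def test_zero_weights_give_half(self):
        net = LSTMNetwork(NetworkConfig(units=(3, 3, 3), seed=0))
        for p in net.params:
            p[...] = 0.0
        probs = net.forward(np.zeros((15, 60)))
        np.testing.assert_allclose(probs, 0.5)

    def test_wrong_shape_rejected(self):
        net = LSTMNetwork(NetworkConfig(units=(3, 3, 3), seed=0))
        with pytest.raises(ValidationError):
            net.forward(np.zeros((14, 60)))

    def test_deterministic_inference(self):
        net = LSTMNetwork(NetworkConfig(units=(4, 4, 4), seed=3))
        w = np.random.default_rng(1).random((15, 60))
        assert np.array_equal(net.forward(w), net.forward(w))

    def test_output_heads_are_independent(self):
        net = LSTMNetwork(NetworkConfig(units=(4, 4, 4), seed=5))
        w = np.random.default_rng(2).random((15, 60))
        before = net.forward(w)
        net.Wd[:, 0] += 1.0  # perturb only the flapping head
        net.bd[0] -= 0.3
        after = net.forward(w)
        assert after[0] != before[0]
        assert after[1] == before[1]


class TestPredict:
    def test_threshold_rule(self):
        net = LSTMNetwork(NetworkConfig(units=(3, 3, 3), seed=0))
        probs = np.array([[0.9, 0.2], [0.5, 0.5], [0.1, 0.8]])
        bits = (probs >= net.config.threshold).astype(int)
        assert bits.tolist() == [[1, 0], [1, 1], [0, 1]]

    def test_all_label_combinations_reachable(self, small_windows):
        from mannerkit.features import windows_to_arrays
        bal = mk.select_and_balance(small_windows, seed=0)
        X, Y, _ = windows_to_arrays(bal)
        net, _ = train(X, Y, mk.desk_config(seed=2, epochs=20))
        preds = {tuple(p) for p in net.predict(X)}
        assert preds == {(0, 0), (1, 0), (0, 1), (1, 1)}


class TestTrain:
    def test_loss_decreases_on_clean_windows(self, small_windows):
        from mannerkit.features import windows_to_arrays
        bal = mk.select_and_balance(small_windows, seed=0)
        X, Y, _ = windows_to_arrays(bal)
        _, hist = train(X, Y, mk.desk_config(seed=1, epochs=15))
        assert hist[-1] < hist[0]
        assert hist[-1] < 0.3

    def test_overfits_single_example(self):
        rng = np.random.default_rng(0)
        X = rng.random((1, 15, 60))
        Y = np.array([[1.0, 0.0]])
        cfg = NetworkConfig(units=(8, 8, 8), batch_size=1, learning_rate=0.05,
                            epochs=300, seed=4)
        _, hist = train(X, Y, cfg)
        assert hist[-1] < 0.05

    def test_same_seed_identical_history(self):
        rng = np.random.default_rng(1)
        X = rng.random((24, 15, 60))
        Y = rng.integers(0, 2, (24, 2)).astype(float)
        cfg = NetworkConfig(units=(4, 4, 4), batch_size=8, epochs=5, seed=9)
        _, h1 = train(X, Y, cfg)
        _, h2 = train(X, Y, cfg)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            train(np.zeros((0, 15, 60)), np.zeros((0, 2)),
                  NetworkConfig(units=(2, 2, 2)))

    def test_uninformative_input_converges_to_ln2(self):
        """With identical inputs and balanced random labels the best any
        predictor can do is p = 0.5, i.e. loss ln 2 per output."""
        rng = np.random.default_rng(6)
        X = np.tile(rng.random((1, 15, 60)), (64, 1, 1))
        y = np.concatenate([np.zeros(32), np.ones(32)])
        rng.shuffle(y)
        Y = np.stack([y, 1 - y], axis=1)
        cfg = NetworkConfig(units=(4, 4, 4), batch_size=16, learning_rate=0.003,
                            epochs=20, seed=2)
        _, hist = train(X, Y, cfg)
        assert abs(hist[-1] - math.log(2)) < 0.05


class TestPortable:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        X = rng.random((16, 15, 60))
        Y = rng.integers(0, 2, (16, 2)).astype(float)
        cfg = NetworkConfig(units=(4, 4, 4), batch_size=8, epochs=2, seed=1)
        net, _ = train(X, Y, cfg)
        net.save_portable(tmp_path / "model")
        again = LSTMNetwork.load_portable(tmp_path / "model")
        np.testing.assert_array_equal(net.predict_proba(X), again.predict_proba(X))

    def test_reference_cell_can_reload_engine_weights(self, tmp_path):
        net = LSTMNetwork(NetworkConfig(units=(3, 3, 3), seed=2),
                          input_size=4, timesteps=5)
        net.save_portable(tmp_path / "m")
        again = LSTMNetwork.load_portable(tmp_path / "m")
        xs = np.random.default_rng(0).normal(size=(5, 4))
        ref = run_lstm_sequence(xs, again.layers[0].cell_params())
        eng, _ = net.layers[0].forward(xs[None])
        np.testing.assert_allclose(ref, eng[0], atol=1e-12)
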