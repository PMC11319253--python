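"""FCN+NLSTM classifier: blocks, the nested cell, training and prediction."""

import numpy as np
import pytest

from ictalnet.model import (
    ConvSpec,
    FCNLSTM,
    ModelConfig,
    NLSTMCell,
    conv_block_forward,
    load_checkpoint,
    predict,
    save_checkpoint,
    small_config,
    train,
)
from ictalnet.model import forward as model_forward
from ictalnet.nn import Tensor


def tiny_config(**over):
    base = dict(
        conv=(ConvSpec(3, 4, 1), ConvSpec(3, 4, 1), ConvSpec(2, 4, 1)),
        hidden=6,
        inner_hidden=6,
        fc_width=6,
        epochs=30,
        batch_size=16,
        lr=5e-3,
        seed=0,
        early_stop_patience=30,
    )
    base.update(over)
    return ModelConfig(**base)


def blob_data(rng, n=200, steps=8, feats=4):
    half = n // 2
    x = np.concatenate(
        [rng.normal(-1.0, 0.3, (half, steps, feats)), rng.normal(1.0, 0.3, (half, steps, feats))]
    )
    y = np.array([0] * half + [1] * half)
    perm = rng.permutation(n)
    return x[perm], y[perm]


class TestConvBlock:
    def test_zero_weights_give_zero_output(self, rng):
        x = rng.standard_normal((10, 3))
        out = conv_block_forward(x, np.zeros((3, 3, 5)), np.zeros(5))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_kernel_on_nonnegative_input(self, rng):
        x = np.abs(rng.standard_normal((10, 1)))
        w = np.ones((1, 1, 1))
        out = conv_block_forward(x, w, np.zeros(1))
        np.testing.assert_allclose(out, x)

    def test_matches_sliding_dot_product_oracle(self, rng):
        x = rng.standard_normal((8, 2))
        w = rng.standard_normal((3, 2, 4))
        b = rng.standard_normal(4)
        out = conv_block_forward(x, w, b, stride=1)
        for t in range(6):
            for co in range(4):
                acc = b[co] + sum(
                    x[t + k, c] * w[k, c, co] for k in range(3) for c in range(2)
                )
                assert out[t, co] == pytest.approx(max(acc, 0.0), abs=1e-6)


class TestNLSTMCell:
    def test_zero_weights_zero_state_zero_input(self, rng):
        cell = NLSTMCell(3, 4, rng)
        for p in cell.params:
            p.data[:] = 0.0
        h, (h2, c2, ci2) = cell.step(
            Tensor(np.zeros((1, 3))), cell.initial_state(1)
        )
        np.testing.assert_array_equal(h.data, 0.0)
        np.testing.assert_array_equal(c2.data, 0.0)
        np.testing.assert_array_equal(ci2.data, 0.0)

    def test_additive_inner_reduces_to_standard_lstm(self, rng):
        """The normative oracle: inner-cell-as-addition == textbook LSTM."""

        def ref_lstm_step(x, h, c, W, b):
            z = np.concatenate([x, h], axis=1) @ W + b
            H = h.shape[1]
            sig = lambda v: 1.0 / (1.0 + np.exp(-v))
            i, f = sig(z[:, :H]), sig(z[:, H : 2 * H])
            g, o = np.tanh(z[:, 2 * H : 3 * H]), sig(z[:, 3 * H :])
            c2 = f * c + i * g
            return o * np.tanh(c2), c2

        for _ in range(20):
            cell = NLSTMCell(5, 4, rng, inner_mode="add")
            x = rng.standard_normal((3, 5))
            h = rng.standard_normal((3, 4))
            c = rng.standard_normal((3, 4))
            ht, (_, ct, _) = cell.step(
                Tensor(x), (Tensor(h), Tensor(c), Tensor(np.zeros((3, 4))))
            )
            h_ref, c_ref = ref_lstm_step(x, h, c, cell.W.data, cell.b.data)
            np.testing.assert_allclose(ht.data, h_ref, atol=1e-6)
            np.testing.assert_allclose(ct.data, c_ref, atol=1e-6)

    def test_scalar_cell_matches_hand_computation(self, rng):
        """Size-1 nested cell with hand-set weights vs the written equations."""
        cell = NLSTMCell(1, 1, rng)
        cell.W.data[:] = np.array([[0.5, -0.25, 1.0, 0.75], [0.1, 0.2, 0.3, 0.4]])
        cell.b.data[:] = np.array([0.05, -0.05, 0.0, 0.1])
        cell.W_in.data[:] = np.array([[0.6, 0.2, -0.4, 0.3], [-0.1, 0.5, 0.2, 0.8]])
        cell.b_in.data[:] = np.array([0.0, 0.1, -0.1, 0.2])
        x, h, c, ci = 0.8, -0.3, 0.4, 0.2

        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        z = np.array([x, h]) @ cell.W.data + cell.b.data
        i, f, g, o = sig(z[0]), sig(z[1]), np.tanh(z[2]), sig(z[3])
        z2 = np.array([i * g, f * c]) @ cell.W_in.data + cell.b_in.data
        i2, f2, g2, o2 = sig(z2[0]), sig(z2[1]), np.tanh(z2[2]), sig(z2[3])
        ci_t = f2 * ci + i2 * g2
        c_t = o2 * np.tanh(ci_t)
        h_expected = o * np.tanh(c_t)

        ht, (_, ct, cit) = cell.step(
            Tensor([[x]]), (Tensor([[h]]), Tensor([[c]]), Tensor([[ci]]))
        )
        assert ht.data[0, 0] == pytest.approx(h_expected, abs=1e-12)
        assert ct.data[0, 0] == pytest.approx(c_t, abs=1e-12)
        assert cit.data[0, 0] == pytest.approx(ci_t, abs=1e-12)


class TestForward:
    def test_probabilities_on_simplex(self, rng):
        net = FCNLSTM(tiny_config(), n_features=4)
        p = net.predict_proba(rng.standard_normal((9, 8, 4)) * 10)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_batch_permutation_equivariance(self, rng):
        net = FCNLSTM(tiny_config(), n_features=4)
        x = rng.standard_normal((6, 8, 4))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            net.predict_proba(x)[perm], net.predict_proba(x[perm]), atol=1e-12
        )

    def test_shape_mismatch_is_an_error(self, rng):
        net = FCNLSTM(tiny_config(), n_features=4)
        with pytest.raises(ValueError, match="expected input"):
            net.forward(rng.standard_normal((2, 8, 5)))


class TestTraining:
    def test_same_seed_reproduces_predictions_exactly(self, rng):
        x, y = blob_data(rng)
        cfg = tiny_config(epochs=5)
        m1 = train(x[:150], y[:150], cfg)
        m2 = train(x[:150], y[:150], tiny_config(epochs=5))
        p1 = model_forward(m1, x[150:])
        p2 = model_forward(m2, x[150:])
        np.testing.assert_array_equal(p1, p2)

    def test_loss_decreases_from_initialization(self, rng):
        x, y = blob_data(rng)
        m = train(x, y, tiny_config(epochs=10))
        assert m.training_log[-1] < m.training_log[0]

    def test_separable_blobs_reach_high_training_accuracy(self, rng):
        x, y = blob_data(rng, n=200)
        m = train(x, y, tiny_config(epochs=50))
        labels, _ = predict(m, x)
        assert np.mean(labels == y) >= 0.99

    def test_single_class_training_set_rejected(self, rng):
        x = rng.standard_normal((10, 8, 4))
        with pytest.raises(ValueError, match="single class"):
            train(x, np.zeros(10, dtype=int), tiny_config())


class TestPredict:
    def test_argmax_and_threshold_agree_for_binary(self, rng):
        x, y = blob_data(rng)
        m = train(x, y, tiny_config(epochs=10))
        labels, probs = predict(m, x)
        np.testing.assert_array_equal(labels, (probs[:, 1] > 0.5).astype(int))

    def test_exact_tie_breaks_to_lowest_class_index(self):
        cfg = tiny_config()
        net = FCNLSTM(cfg, n_features=4)
        net.out_w.data[:] = 0.0
        net.out_b.data[:] = 0.0
        from ictalnet.model import TrainedModel

        m = TrainedModel(config=cfg, net=net, class_order=[0, 1])
        labels, probs = predict(m, np.ones((3, 8, 4)))
        np.testing.assert_allclose(probs, 0.5)
        np.testing.assert_array_equal(labels, 0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        x, y = blob_data(rng)
        m = train(x, y, tiny_config(epochs=3))
        path = save_checkpoint(m, tmp_path / "model.npz")
        m2 = load_checkpoint(path)
        np.testing.assert_array_equal(model_forward(m, x), model_forward(m2, x))
        assert m2.config == m.config
        assert m2.seed == m.seed


class TestModelConfig:
    def test_exactly_three_conv_blocks_required(self):
        with pytest.raises(ValueError, match="3 conv blocks"):
            ModelConfig(conv=(ConvSpec(3, 4, 1), ConvSpec(3, 4, 1)))

    def test_inner_hidden_must_equal_outer(self):
        with pytest.raises(ValueError, match="inner_hidden"):
            ModelConfig(hidden=8, inner_hidden=4)

    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError, match="input_layout"):
            ModelConfig(input_layout="columns_as_steps")

    def test_dict_round_trip(self):
        cfg = small_config(seed=9)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
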