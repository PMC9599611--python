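import numpy as np
import pytest

from lsrnet import (
    Stage2Model,
    bilstm_features,
    fuse_and_classify,
    global_cnn_features,
    predict_scan,
    train_stage2,
)
from lsrnet.nn import LSTMLayer, softmax

from test_nn import reference_lstm


def brute_force_global_conv(latent, kernels, biases):
    m, h = latent.shape
    out = np.zeros(len(kernels))
    for k in range(len(kernels)):
        s = 0.0
        for i in range(m):
            for j in range(h):
                s += latent[i, j] * kernels[k, i, j]
        out[k] = np.tanh(s + biases[k])
    return out


class TestGlobalCnn:
    def test_zero_kernel_gives_zero(self, rng):
        latent = rng.uniform(-1, 1, (6, 4))
        out = global_cnn_features(latent, np.zeros((3, 6, 4)), np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_indicator_kernel_picks_entry(self, rng):
        latent = rng.uniform(-1, 1, (6, 4))
        kernel = np.zeros((1, 6, 4))
        kernel[0, 2, 3] = 1.0
        out = global_cnn_features(latent, kernel, np.zeros(1), activation=None)
        assert out[0] == pytest.approx(latent[2, 3], abs=1e-15)

    def test_matches_brute_force_double_loop(self, rng):
        latent = rng.uniform(-1, 1, (5, 7))
        kernels = rng.standard_normal((8, 5, 7))
        biases = rng.standard_normal(8)
        np.testing.assert_allclose(
            global_cnn_features(latent, kernels, biases),
            brute_force_global_conv(latent, kernels, biases),
            atol=1e-10,
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            global_cnn_features(np.zeros((4, 3)), np.zeros((2, 5, 3)), np.zeros(2))


class TestBilstmFeatures:
    def test_output_length_is_twice_hidden(self, rng):
        fw, bw = LSTMLayer(4, 32, rng), LSTMLayer(4, 32, rng)
        out = bilstm_features(rng.standard_normal((6, 4)), fw, bw)
        assert out.shape == (64,)

    def test_matches_reference_recurrence(self, rng):
        fw, bw = LSTMLayer(2, 3, rng), LSTMLayer(2, 3, rng)
        x = rng.standard_normal((3, 2))
        got = bilstm_features(x, fw, bw)
        ref_fw = reference_lstm(x, fw.w, fw.u, fw.b)[-1]
        ref_bw = reference_lstm(x[::-1], bw.w, bw.u, bw.b)[-1]
        np.testing.assert_allclose(got, np.concatenate([ref_fw, ref_bw]), atol=1e-10)

    def test_reversed_input_swaps_direction_blocks(self, rng):
        # mirrored parameters: reversing the windows exchanges the roles of
        # the forward and backward passes exactly
        fw, bw = LSTMLayer(3, 4, rng), LSTMLayer(3, 4, rng)
        x = rng.standard_normal((5, 3))
        ab = bilstm_features(x, fw, bw)
        ba = bilstm_features(x[::-1], bw, fw)
        np.testing.assert_allclose(ab, np.concatenate([ba[4:], ba[:4]]), atol=1e-12)


class TestFuseAndClassify:
    def _model(self, rng, n_classes=2):
        return Stage2Model(4, 3, n_classes, n_kernels=2, lstm_hidden=2,
                           fusion_hidden=4, rng=rng)

    def test_probabilities_on_simplex(self, rng):
        m = self._model(rng, n_classes=4)
        probs = fuse_and_classify(rng.standard_normal(2),
                                  rng.standard_normal(4), m.fusion)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_logits_symmetric(self, rng):
        m = self._model(rng)
        for layer in m.fusion.layers:
            for p in layer.params:
                p[...] = 0.0
        probs = fuse_and_classify(np.ones(2), np.ones(4), m.fusion)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_softmax_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([1.0, 2.0])), [0.26894142137, 0.73105857863],
            atol=1e-9,
        )


class TestTrainStage2:
    @pytest.fixture(scope="class")
    @staticmethod
    def toy_data():
        # two latent-sequence classes separated by mean shift
        rng = np.random.default_rng(4)
        m, h, per = 6, 5, 20
        x0 = np.tanh(rng.standard_normal((per, m, h)) * 0.3 - 0.4)
        x1 = np.tanh(rng.standard_normal((per, m, h)) * 0.3 + 0.4)
        x = np.concatenate([x0, x1])
        y = np.array([0] * per + [1] * per)
        return x, y

    def test_loss_decreases_and_separates(self, toy_data):
        x, y = toy_data
        model, hist = train_stage2(
            x, y, n_classes=2, epochs=30, seed=0,
            n_kernels=4, lstm_hidden=4, fusion_hidden=4,
        )
        assert hist["train_loss"][-1] <= hist["train_loss"][0]
        preds = np.argmax(model.predict_proba(x), axis=1)
        assert np.mean(preds == y) > 0.9

    def test_same_seed_identical(self, toy_data):
        x, y = toy_data
        m1, h1 = train_stage2(x, y, n_classes=2, epochs=5, seed=7,
                              n_kernels=4, lstm_hidden=4)
        m2, h2 = train_stage2(x, y, n_classes=2, epochs=5, seed=7,
                              n_kernels=4, lstm_hidden=4)
        assert h1["train_loss"] == h2["train_loss"]
        for p, q in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p, q)
        np.testing.assert_array_equal(m1.predict_proba(x), m2.predict_proba(x))

    def test_single_class_rejected(self, toy_data):
        x, _ = toy_data
        with pytest.raises(ValueError, match="single class"):
            train_stage2(x, np.zeros(len(x), dtype=int), n_classes=2, epochs=1)

    def test_single_perspective_variants_train(self, toy_data):
        x, y = toy_data
        for kw in (dict(use_df=False), dict(use_gf=False)):
            model, _ = train_stage2(x, y, n_classes=2, epochs=5, seed=0,
                                    n_kernels=4, lstm_hidden=4, **kw)
            assert model.predict_proba(x).shape == (len(x), 2)

    def test_all_steps_df_mode(self, toy_data):
        x, y = toy_data
        model, _ = train_stage2(x, y, n_classes=2, epochs=3, seed=0,
                                use_gf=False, lstm_hidden=4, df_mode="all_steps")
        assert model.feature_dim == 2 * 4 * x.shape[1]

    def test_prediction_batch_invariance(self, toy_data):
        x, y = toy_data
        model, _ = train_stage2(x, y, n_classes=2, epochs=3, seed=0,
                                n_kernels=4, lstm_hidden=4)
        batched = model.predict_proba(x)
        singly = np.vstack([model.predict_proba(xi[None]) for xi in x])
        np.testing.assert_allclose(batched, singly, atol=1e-12)


class TestPredictScan:
    def test_argmax_and_tie_break(self, rng):
        model, _ = train_stage2(
            np.tanh(rng.standard_normal((10, 4, 3))),
            np.array([0, 1] * 5), n_classes=2, epochs=2, seed=0,
            n_kernels=2, lstm_hidden=2,
        )
        pred, probs = predict_scan(np.tanh(rng.standard_normal((4, 3))), model)
        assert pred == int(np.argmax(probs))
        # exact tie breaks to the lowest class id
        assert int(np.argmax(np.array([0.5, 0.5]))) == 0

    def test_shape_mismatch_rejected(self, rng):
        model, _ = train_stage2(
            np.tanh(rng.standard_normal((10, 4, 3))),
            np.array([0, 1] * 5), n_classes=2, epochs=1, seed=0,
            n_kernels=2, lstm_hidden=2,
        )
        with pytest.raises(ValueError):
            predict_scan(np.zeros((5, 3)), model)


def test_stage2_gradients_match_finite_differences(rng):
    """End-to-end gradient check through GCNN + BiLSTM + FusionNet."""
    from lsrnet.nn import cross_entropy_grad, cross_entropy_loss

    model = Stage2Model(3, 2, 2, n_kernels=2, lstm_hidden=2, fusion_hidden=3,
                        rng=rng)
    x = rng.standard_normal((4, 3, 2))
    y = np.array([0, 1, 1, 0])

    def loss():
        return cross_entropy_loss(model.forward(x, train=True), y)

    logits = model.forward(x, train=True)
    for g in model.grads:
        g[...] = 0.0
    model.backward(cross_entropy_grad(logits, y))
    from test_nn import numerical_grad

    for p, g in zip(model.params, model.grads):
        num = numerical_grad(loss, p)
        np.testing.assert_allclose(g, num, atol=1e-6, rtol=1e-4)
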