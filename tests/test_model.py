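"""Per-modality network and fusion head: shapes, attention algebra, gradients."""

import numpy as np
import pytest

from falarm import (
    ContractError,
    FusionHead,
    ModalConfig,
    ModalNet,
    ShapeError,
    attention_step,
    cnn_features,
    fuse_forward,
    load_checkpoint,
    save_checkpoint,
)
from falarm.losses import LossKind, batch_loss, loss_gradient
from falarm.network import FeatureSlices


@pytest.fixture(scope="module")
def default_net():
    return ModalNet(ModalConfig(), seed=0)


class TestCnnFeatures:
    def test_five_slice_output_is_5_by_64(self):
        """The printed-architecture shape: 64 feature maps pooled to 5 x 1."""
        net = ModalNet(ModalConfig(n_slices=5), seed=0)
        slices = cnn_features(np.random.default_rng(0).random(200), net)
        assert slices.C.shape == (5, 64)

    def test_default_ten_slice_variant(self, default_net):
        assert cnn_features(np.zeros(200), default_net).C.shape == (10, 64)

    def test_zero_parameters_give_zero_output(self, default_net):
        net = default_net.copy()
        for v in net.params.values():
            v[...] = 0.0
        out = cnn_features(np.random.default_rng(1).random(200), net).C
        np.testing.assert_array_equal(out, 0.0)

    def test_outputs_nonnegative_post_relu(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            net = ModalNet(ModalConfig(), seed=seed)
            assert cnn_features(rng.standard_normal(200), net).C.min() >= 0.0

    def test_wrong_length_rejected(self, default_net):
        with pytest.raises(ShapeError):
            cnn_features(np.zeros(100), default_net)


class TestAttention:
    def test_identical_slices_give_uniform_weights(self, default_net):
        slice_ = np.random.default_rng(3).random(64)
        C = np.tile(slice_, (5, 1))
        state = attention_step(C, np.zeros(256), default_net)
        np.testing.assert_allclose(state.alpha, 0.2, atol=1e-6)
        np.testing.assert_allclose(state.context, slice_, atol=1e-5)

    def test_hand_computed_softmax_of_scores_1_2(self):
        """With A=1, W_h=0, W_C=[[1]], v=[4] and slices atanh(1/4), atanh(2/4),
        the scores are exactly [1, 2] and alpha = softmax([1, 2])."""
        cfg = ModalConfig(n=40, conv1_filters=2, conv2_filters=1, n_slices=2,
                          attention_width=1, lstm_size=4, fc_size=4, dtype="float64")
        net = ModalNet(cfg, seed=0)
        net.params["W_h"][...] = 0.0
        net.params["W_C"][...] = 1.0
        net.params["v_att"][...] = 4.0
        C = np.array([[np.arctanh(0.25)], [np.arctanh(0.5)]])
        state = attention_step(C, np.zeros(4), net)
        np.testing.assert_allclose(state.alpha, [0.26894142, 0.73105858], atol=1e-7)

    def test_simplex_and_convex_hull_invariants(self):
        """1000 random draws: alpha lies on the simplex and the context in the
        per-dimension convex hull of the slices."""
        cfg = ModalConfig(n_slices=5, conv2_filters=16, attention_width=8,
                          lstm_size=12, dtype="float64")
        rng = np.random.default_rng(4)
        for i in range(1000):
            if i % 100 == 0:
                net = ModalNet(cfg, seed=i)
            C = rng.standard_normal((5, 16))
            h = rng.standard_normal(12)
            state = attention_step(C, h, net)
            assert np.all(state.alpha >= 0)
            assert abs(state.alpha.sum() - 1.0) < 1e-6
            assert np.all(state.context >= C.min(axis=0) - 1e-9)
            assert np.all(state.context <= C.max(axis=0) + 1e-9)

    def test_single_slice_reduces_to_identity(self):
        cfg = ModalConfig(n_slices=1, dtype="float64")
        net = ModalNet(cfg, seed=1)
        C = np.random.default_rng(5).random((1, 64))
        state = attention_step(C, np.random.default_rng(6).random(256), net)
        assert state.alpha[0] == pytest.approx(1.0)
        np.testing.assert_allclose(state.context, C[0], atol=1e-12)


class TestForward:
    def test_probs_form_distribution(self, tiny_modal_config):
        rng = np.random.default_rng(7)
        for seed in range(5):
            net = ModalNet(tiny_modal_config, seed=seed)
            probs, emb, _ = net.forward(rng.random((3, 4, 40)))
            assert np.all(probs >= 0)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_embedding_size_256_by_default(self):
        net = ModalNet(ModalConfig(), seed=0)
        _, emb, _ = net.forward(np.random.default_rng(8).random((1, 3, 200)))
        assert emb.shape == (1, 256)

    def test_repeat_call_is_bit_identical(self, tiny_modal_config):
        net = ModalNet(tiny_modal_config, seed=3)
        X = np.random.default_rng(9).random((2, 5, 40))
        p1, e1, _ = net.forward(X)
        p2, e2, _ = net.forward(X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(e1, e2)

    def test_empty_sequence_rejected(self, tiny_modal_config):
        from falarm import InsufficientDataError

        net = ModalNet(tiny_modal_config, seed=0)
        with pytest.raises((InsufficientDataError, ShapeError)):
            net.forward(np.zeros((2, 0, 40)))

    def test_disabled_attention_is_uniform_average(self, tiny_modal_config):
        """With attention off, the context must equal the slice mean."""
        from dataclasses import replace

        cfg = replace(tiny_modal_config, attention_enabled=False)
        net = ModalNet(cfg, seed=2)
        C = np.random.default_rng(10).random((2, 4))
        state = attention_step(FeatureSlices(C), np.zeros(5), net)
        np.testing.assert_allclose(state.context, C.mean(axis=0), atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("kind", list(LossKind))
    def test_backprop_matches_finite_differences(self, tiny_modal_config, kind):
        """Hand-derived backprop through softmax/FC/LSTM/attention/CNN agrees
        with central finite differences on every parameter tensor."""
        rng = np.random.default_rng(0)
        net = ModalNet(tiny_modal_config, seed=1)
        X = rng.random((3, 4, 40))
        y = np.array([0, 1, 1])
        probs, _, cache = net.forward(X, need_cache=True)
        grads = net.backward(cache, loss_gradient(probs, y, kind))
        eps = 1e-6
        for name, p in net.params.items():
            flat_idx = rng.choice(p.size, size=min(5, p.size), replace=False)
            for i in flat_idx:
                ix = np.unravel_index(i, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = batch_loss(net.forward(X)[0], y, kind)
                p[ix] = orig - eps
                lm = batch_loss(net.forward(X)[0], y, kind)
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][ix]
                assert ana == pytest.approx(num, rel=5e-3, abs=1e-8), name

    def test_attention_disabled_gradients_also_exact(self, tiny_modal_config):
        from dataclasses import replace

        rng = np.random.default_rng(1)
        net = ModalNet(replace(tiny_modal_config, attention_enabled=False), seed=1)
        X = rng.random((2, 3, 40))
        y = np.array([0, 1])
        probs, _, cache = net.forward(X, need_cache=True)
        grads = net.backward(cache, loss_gradient(probs, y, LossKind.MFE))
        eps = 1e-6
        for name in ("W_conv1", "W_lstm1", "W_fc"):
            p = net.params[name]
            ix = np.unravel_index(int(rng.integers(p.size)), p.shape)
            orig = p[ix]
            p[ix] = orig + eps
            lp = batch_loss(net.forward(X)[0], y, LossKind.MFE)
            p[ix] = orig - eps
            lm = batch_loss(net.forward(X)[0], y, LossKind.MFE)
            p[ix] = orig
            assert grads[name][ix] == pytest.approx((lp - lm) / (2 * eps), rel=5e-3, abs=1e-9)


class TestFusion:
    def test_identical_embeddings_average_to_themselves(self):
        head = FusionHead(embed_size=8, seed=0, fc_size=4, dtype="float64")
        e = np.random.default_rng(11).random(8)
        probs_same = fuse_forward(e, e, e, head)
        probs_direct, _ = head.forward(e[None])
        np.testing.assert_allclose(probs_same, probs_direct[0], atol=1e-12)

    def test_elementwise_mean(self):
        head = FusionHead(embed_size=3, seed=0, dtype="float64")
        a, b, c = np.array([0.0, 2, 4]), np.array([2.0, 4, 0]), np.array([4.0, 0, 2])
        expected, _ = head.forward(np.array([[2.0, 2, 2]]))
        np.testing.assert_allclose(fuse_forward(a, b, c, head), expected[0], atol=1e-12)

    def test_inference_has_no_dropout_noise(self):
        head = FusionHead(embed_size=16, seed=0)
        e = np.random.default_rng(12).random((4, 16))
        p1, _ = head.forward(e, training=False)
        p2, _ = head.forward(e, training=False)
        np.testing.assert_array_equal(p1, p2)

    def test_training_dropout_needs_rng_and_differs(self):
        head = FusionHead(embed_size=16, seed=0)
        e = np.random.default_rng(13).random((4, 16))
        with pytest.raises(ContractError):
            head.forward(e, training=True)
        p_train, _ = head.forward(e, training=True, rng=np.random.default_rng(1))
        p_eval, _ = head.forward(e, training=False)
        assert not np.allclose(p_train, p_eval)

    def test_dimension_mismatch(self):
        head = FusionHead(embed_size=8, seed=0)
        with pytest.raises(ShapeError):
            fuse_forward(np.zeros(8), np.zeros(8), np.zeros(7), head)


class TestCheckpoint:
    def test_round_trip(self, tiny_modal_config, tmp_path):
        net = ModalNet(tiny_modal_config, seed=4)
        net.frozen = True
        path = save_checkpoint(net, tmp_path / "net")
        back = load_checkpoint(path)
        assert back.frozen and not back.stripped
        assert back.config == net.config
        for k in net.params:
            np.testing.assert_array_equal(back.params[k], net.params[k])
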