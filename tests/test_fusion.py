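"""Fusion heads: fusion ops, batch norm, architecture, training behavior."""

import numpy as np
import pytest

from cadeye import DataError, ParameterError, ShapeError
from cadeye.backbones import build_backbone, checksum
from cadeye.fusion import (BatchNormParams, batch_norm, build_fusion_model,
                           count_parameters, fuse, load_fusion_model,
                           predict_proba_features, save_fusion_model, train,
                           train_on_features)


class TestFuse:
    def test_concat(self):
        out = fuse(np.array([[1.0, 2.0]]), np.array([[3.0]]), "concat")
        assert out.tolist() == [[1.0, 2.0, 3.0]]

    def test_sum_with_identity_transforms(self):
        out = fuse(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]), "sum")
        assert out.tolist() == [[4.0, 6.0]]

    def test_product_with_identity_transforms(self):
        out = fuse(np.array([[2.0, 3.0]]), np.array([[4.0, 5.0]]), "product")
        assert out.tolist() == [[8.0, 15.0]]

    def test_width_mismatch_without_transform(self):
        with pytest.raises(ShapeError):
            fuse(np.ones((1, 2)), np.ones((1, 3)), "sum")

    def test_unknown_mode(self):
        with pytest.raises(ParameterError):
            fuse(np.ones((1, 2)), np.ones((1, 2)), "average")


class TestBatchNorm:
    def test_hand_evaluated_two_sample_batch(self):
        p = BatchNormParams.create(1)
        out = batch_norm(np.array([[2.0], [4.0]]), p, training=True)
        expected = 1.0 / np.sqrt(1.0 + p.epsilon)   # mu=3, sigma^2=1
        assert out[:, 0] == pytest.approx([-expected, expected], abs=1e-6)

    def test_gamma_zero_gives_constant_beta(self, rng):
        p = BatchNormParams.create(3)
        p.gamma[...] = 0.0
        p.beta[...] = 1.5
        out = batch_norm(rng.random((8, 3)), p, training=True)
        assert np.allclose(out, 1.5)

    def test_statistical_moments(self, rng):
        """Post-normalization batch mean equals beta and variance equals
        gamma^2 (after the epsilon shrinkage correction)."""
        p = BatchNormParams.create(4, epsilon=1e-5)
        p.gamma[...] = np.array([1.0, 2.0, 0.5, 3.0], dtype=np.float32)
        p.beta[...] = np.array([0.0, -1.0, 2.0, 0.25], dtype=np.float32)
        x = rng.normal(5.0, 2.0, size=(64, 4))
        out = batch_norm(x, p, training=True)
        v = x.astype(np.float32).var(axis=0)
        expected_var = p.gamma ** 2 * v / (v + p.epsilon)
        assert np.allclose(out.mean(axis=0), p.beta, atol=1e-5)
        assert np.allclose(out.var(axis=0), expected_var, atol=1e-4)

    def test_training_needs_two_samples(self):
        with pytest.raises(DataError):
            batch_norm(np.ones((1, 2)), BatchNormParams.create(2), training=True)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ParameterError):
            BatchNormParams.create(2, epsilon=0.0)


class TestArchitecture:
    def test_basic_head_shapes(self, rng):
        m = build_fusion_model(24, 32, num_classes=5, variant="basic", seed=0)
        assert m.layers[0].w.shape == (56, 128)
        probs = m.forward(rng.random((3, 24)), rng.random((3, 32)))
        assert probs.shape == (3, 5)

    def test_basic_head_parameter_count_closed_form(self):
        ca, cb, k = 24, 32, 5
        m = build_fusion_model(ca, cb, k, "basic", "concat", seed=0)
        assert count_parameters(m) == (ca + cb + 1) * 128 + 129 * k

    def test_extended_head_structure(self, rng):
        from cadeye.fusion import _DenseBlock
        m = build_fusion_model(24, 32, 5, "extended", seed=0)
        blocks = [l for l in m.layers if isinstance(l, _DenseBlock)]
        assert len(blocks) == 3
        assert m.output.w.shape[0] == 850
        assert m.penultimate(rng.random((2, 24)), rng.random((2, 32))).shape == (2, 850)

    def test_invalid_variant(self):
        with pytest.raises(ParameterError):
            build_fusion_model(4, 4, 5, variant="huge")
        with pytest.raises(ParameterError):
            build_fusion_model(4, 4, 1, variant="basic")

    def test_softmax_normalization_and_uniform_logits(self, rng):
        m = build_fusion_model(6, 6, 5, "basic", seed=1)
        probs = m.forward(rng.random((4, 6)), rng.random((4, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()
        m.output.w[...] = 0.0
        m.output.b[...] = 0.0
        probs = m.forward(rng.random((4, 6)), rng.random((4, 6)))
        assert np.allclose(probs, 0.2, atol=1e-6)


def _cluster_features(rng, n_per_class=30, k=5, d_a=8, d_b=6):
    centers_a = rng.normal(0, 3, size=(k, d_a))
    centers_b = rng.normal(0, 3, size=(k, d_b))
    fa, fb, y = [], [], []
    for c in range(k):
        fa.append(centers_a[c] + rng.normal(0, 0.5, size=(n_per_class, d_a)))
        fb.append(centers_b[c] + rng.normal(0, 0.5, size=(n_per_class, d_b)))
        y.extend([c] * n_per_class)
    return np.vstack(fa), np.vstack(fb), np.array(y)


class TestTraining:
    def test_zero_epochs_changes_nothing(self, rng):
        fa, fb, y = _cluster_features(rng)
        m = build_fusion_model(8, 6, 5, "basic", seed=0)
        before = [p.copy() for p in m.params()]
        history = train_on_features(m, fa, fb, y, epochs=0, seed=0)
        assert history == []
        for p, q in zip(m.params(), before):
            assert np.array_equal(p, q)

    @pytest.mark.parametrize("variant", ["basic", "extended"])
    def test_learning_improves_on_separable_clusters(self, rng, variant):
        fa, fb, y = _cluster_features(rng)
        m = build_fusion_model(8, 6, 5, variant, seed=0)
        history = train_on_features(m, fa, fb, y, epochs=15, seed=0)
        assert len(history) == 15
        assert history[-1]["train_acc"] > history[0]["train_acc"]
        assert history[-1]["train_acc"] > 0.9

    def test_empty_training_split_rejected(self):
        m = build_fusion_model(4, 4, 5, "basic", seed=0)
        with pytest.raises(DataError):
            train_on_features(m, np.empty((0, 4)), np.empty((0, 4)),
                              np.empty(0, dtype=int), epochs=1)

    def test_memorizes_tiny_training_set(self, rng):
        """Capacity sanity: the head can overfit five distinct samples."""
        fa = rng.normal(0, 1, size=(5, 8))
        fb = rng.normal(0, 1, size=(5, 6))
        y = np.arange(5)
        m = build_fusion_model(8, 6, 5, "basic", seed=0)
        train_on_features(m, fa, fb, y, epochs=300, seed=0, batch_size=5,
                          val_fraction=0.0)
        probs = predict_proba_features(m, fa, fb)
        assert (probs.argmax(axis=1) == y).all()

    def test_train_from_manifest_keeps_backbones_frozen(self, tiny_dataset):
        manifest, params, root = tiny_dataset
        bb_a = build_backbone("mobilenet_v2_like", "tiny", 0)
        bb_b = build_backbone("efficientnet_b0_like", "tiny", 0)
        sums = (checksum(bb_a), checksum(bb_b))
        m = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=0)
        history = train(m, (bb_a, bb_b), manifest, epochs=2, seed=0)
        assert len(history) == 2
        assert (checksum(bb_a), checksum(bb_b)) == sums

    def test_sum_and_product_fusion_train(self, rng):
        fa, fb, y = _cluster_features(rng, n_per_class=20)
        for mode in ("sum", "product"):
            m = build_fusion_model(8, 6, 5, "basic", fusion_mode=mode, seed=0)
            history = train_on_features(m, fa, fb, y, epochs=10, seed=0)
            assert history[-1]["train_acc"] > 0.5


def test_checkpoint_roundtrip(tmp_path, rng):
    fa, fb, y = _cluster_features(rng, n_per_class=10)
    m = build_fusion_model(8, 6, 5, "extended", seed=0)
    train_on_features(m, fa, fb, y, epochs=3, seed=0)
    save_fusion_model(m, tmp_path / "head")
    loaded = load_fusion_model(tmp_path / "head")
    assert np.allclose(predict_proba_features(loaded, fa, fb),
                       predict_proba_features(m, fa, fb))
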