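"""Gradient-boosted-tree head: gradients, trees, additivity, cross-checks."""

import json

import numpy as np
import pytest

from cadeye import DataError, ParameterError, ShapeError
from cadeye.gbt import (GBTConfig, GBTEnsemble, _fit_tree, _predict_tree,
                        compute_grad_hess, decision_scores, deep_feature_input,
                        fit_gbt, predict_gbt, training_logloss_curve)
from cadeye.nn import softmax


class TestGradHess:
    def test_perfect_prediction(self):
        g, h = compute_grad_hess(np.array([[1.0, 0.0]]), np.array([0]))
        assert np.allclose(g, 0) and np.allclose(h, 0)

    def test_uniform_binary(self):
        g, h = compute_grad_hess(np.array([[0.5, 0.5]]), np.array([0]))
        assert np.allclose(g, [[-0.5, 0.5]])
        assert np.allclose(h, [[0.25, 0.25]])

    def test_label_out_of_range(self):
        with pytest.raises(DataError):
            compute_grad_hess(np.array([[0.5, 0.5]]), np.array([2]))

    def test_matches_finite_difference(self, rng):
        """g must match the numeric gradient of softmax cross-entropy w.r.t.
        the raw scores."""
        scores = rng.normal(0, 1, size=(6, 4))
        y = rng.integers(0, 4, size=6)
        p = softmax(scores, axis=1)
        g, _ = compute_grad_hess(p, y)
        eps = 1e-6
        for i in range(6):
            for k in range(4):
                sp = scores.copy(); sp[i, k] += eps
                sm = scores.copy(); sm[i, k] -= eps
                lp = -np.log(softmax(sp, axis=1)[i, y[i]])
                lm = -np.log(softmax(sm, axis=1)[i, y[i]])
                assert g[i, k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


def test_leaf_weight_closed_form():
    # constant feature -> no split possible -> single leaf with -G/(H+lam)
    x = np.zeros((2, 1))
    g = np.array([-1.5, -0.5])   # G = -2
    h = np.array([0.5, 0.5])     # H = 1
    tree = _fit_tree(x, g, h, lam=1.0, depth=3)
    assert tree == {"leaf": pytest.approx(1.0)}


def test_lambda_shrinks_leaf_weights(rng):
    for _ in range(50):
        G = rng.normal(0, 2)
        H = abs(rng.normal(0, 1))
        lam_small, lam_big = 0.1, 2.0
        assert abs(-G / (H + lam_big)) <= abs(-G / (H + lam_small)) + 1e-12


def test_zero_rounds_predicts_class_priors(rng):
    x = rng.normal(size=(30, 3))
    y = np.array([0] * 10 + [1] * 10 + [2] * 10)
    ens = fit_gbt(x, y, GBTConfig(tau=0))
    p = predict_gbt(ens, x)
    assert np.allclose(p, 1.0 / 3.0, atol=1e-9)
    # unbalanced priors
    y2 = np.array([0] * 20 + [1] * 10)
    p2 = predict_gbt(fit_gbt(x, y2, GBTConfig(tau=0)), x[:1])
    assert p2[0] == pytest.approx([2 / 3, 1 / 3], abs=1e-9)


def test_separable_stumps_reach_perfect_training_accuracy(rng):
    x = np.concatenate([rng.uniform(-2, -0.1, 25), rng.uniform(0.1, 2, 25)])[:, None]
    y = (x[:, 0] >= 0).astype(int)
    ens = fit_gbt(x, y, GBTConfig(tau=10, max_depth=1))
    assert (predict_gbt(ens, x).argmax(axis=1) == y).all()


def test_training_logloss_non_increasing(rng):
    x = rng.normal(size=(60, 4))
    y = rng.integers(0, 3, size=60)
    curve = training_logloss_curve(x, y, GBTConfig(tau=15, eta=0.3))
    assert (np.diff(curve) <= 1e-9).all()


def test_additivity_of_boosting_rounds(rng):
    x = rng.normal(size=(40, 3))
    y = rng.integers(0, 3, size=40)
    ens = fit_gbt(x, y, GBTConfig(tau=5))
    for t in range(1, 6):
        delta = decision_scores(ens, x, t) - decision_scores(ens, x, t - 1)
        for cls in range(3):
            tree_out = _predict_tree(ens.trees[t - 1][cls], x)
            assert np.allclose(delta[:, cls], ens.config.eta * tree_out)


def test_determinism_and_json_roundtrip(rng):
    x = rng.normal(size=(30, 4))
    y = rng.integers(0, 3, size=30)
    e1 = fit_gbt(x, y, GBTConfig(tau=4, seed=0))
    e2 = fit_gbt(x, y, GBTConfig(tau=4, seed=0))
    assert json.dumps(e1.to_json()) == json.dumps(e2.to_json())
    e3 = GBTEnsemble.from_json(json.loads(json.dumps(e1.to_json())))
    assert np.allclose(predict_gbt(e3, x), predict_gbt(e1, x))


def test_feature_width_mismatch(rng):
    ens = fit_gbt(rng.normal(size=(20, 3)), rng.integers(0, 2, 20), GBTConfig(tau=1))
    with pytest.raises(ShapeError):
        predict_gbt(ens, rng.normal(size=(5, 4)))


def test_invalid_config():
    with pytest.raises(ParameterError):
        GBTConfig(tau=-1)
    with pytest.raises(ParameterError):
        GBTConfig(eta=0.0)


def test_agrees_with_xgboost_on_separable_toy(rng):
    """Cross-implementation check: on a well-separated 50-sample toy the
    reference loop and xgboost assign identical labels."""
    xgboost = pytest.importorskip("xgboost")
    centers = np.array([[-4.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    x = np.vstack([c + rng.normal(0, 0.4, size=(17, 2)) for c in centers])[:50]
    y = np.repeat([0, 1, 2], 17)[:50]
    cfg = GBTConfig(eta=0.3, lam=1.0, tau=10, max_depth=2)
    mine = predict_gbt(fit_gbt(x, y, cfg), x).argmax(axis=1)
    ref = xgboost.XGBClassifier(
        n_estimators=10, learning_rate=0.3, reg_lambda=1.0, max_depth=2,
        min_child_weight=0, gamma=0, tree_method="exact",
        objective="multi:softprob").fit(x, y).predict(x)
    assert (mine == ref).all()


def test_deep_feature_input_contracts(tiny_dataset, rng):
    from cadeye.backbones import build_backbone
    from cadeye.fusion import build_fusion_model
    from cadeye.image import load_image

    manifest, params, root = tiny_dataset
    imgs = [load_image(p) for p in manifest.records["path"][:4]]
    bb_a = build_backbone("mobilenet_v2_like", "tiny", 0)
    bb_b = build_backbone("efficientnet_b0_like", "tiny", 0)
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=0)
    probs = deep_feature_input(model, (bb_a, bb_b), imgs, "probabilities")
    assert probs.shape == (4, 5)
    pen = deep_feature_input(model, (bb_a, bb_b), imgs, "penultimate")
    assert pen.shape == (4, 128)
    with pytest.raises(ParameterError):
        deep_feature_input(model, (bb_a, bb_b), imgs, "logits")
    # identity depthwise kernels reproduce the standard path bit for bit
    pen_dw = deep_feature_input(model, (bb_a, bb_b), imgs, "penultimate",
                                depthwise=True)
    assert np.array_equal(pen, pen_dw)
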