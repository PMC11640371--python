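"""Gradient-boosted regression trees on deep features.

A from-scratch second-order boosting loop for multiclass softmax
cross-entropy, in the style of modern tree-boosting systems: per boosting
round, class probabilities ``p`` give per-sample gradients ``g = p - onehot(y)``
and Hessians ``h = p (1 - p)``; one depth-limited regression tree per class is
fitted to ``(g, h)`` by exact greedy split search maximizing

    gain = 1/2 [ G_L^2/(H_L + lambda) + G_R^2/(H_R + lambda) - G^2/(H + lambda) ]

with leaf weight ``-G/(H + lambda)``; scores accumulate additively with
learning rate ``eta`` over ``tau`` rounds on top of log-prior base scores.

Exact greedy split finding is deterministic given the feature order; no
histogram approximation or column subsampling is used (deep features at desk
scale make them unnecessary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, ShapeError
from .nn import identity_depthwise_kernel, softmax

__all__ = ["GBTConfig", "GBTEnsemble", "compute_grad_hess", "fit_gbt",
           "predict_gbt", "decision_scores", "deep_feature_input"]


@dataclass(frozen=True)
class GBTConfig:
    """Boosting hyperparameters: learning rate ``eta`` in (0, 1], L2 leaf
    regularization ``lam`` >= 0, number of rounds ``tau`` >= 0, tree depth."""

    eta: float = 0.3
    lam: float = 1.0
    tau: int = 50
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.eta <= 1.0:
            raise ParameterError(f"eta must lie in (0, 1], got {self.eta}")
        if self.lam < 0:
            raise ParameterError(f"lambda must be >= 0, got {self.lam}")
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")
        if self.max_depth < 1:
            raise ParameterError(f"max_depth must be >= 1, got {self.max_depth}")


def compute_grad_hess(probabilities: np.ndarray, labels: np.ndarray):
    """Softmax cross-entropy gradients and Hessian diagonals per sample/class."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.ndim != 2:
        raise ShapeError(f"expected a samples x classes matrix, got {p.shape}")
    if y.min(initial=0) < 0 or (len(y) and y.max() >= p.shape[1]):
        raise DataError("label out of range for the probability matrix")
    onehot = np.eye(p.shape[1])[y]
    return p - onehot, p * (1.0 - p)


# ----------------------------------------------------------------------------
# exact-greedy regression tree on (g, h)
# ----------------------------------------------------------------------------

def _fit_tree(x, g, h, lam, depth):
    """Recursive exact-greedy tree; returns a JSON-serializable nested dict."""
    G, H = g.sum(), h.sum()
    if depth == 0 or len(g) < 2:
        return {"leaf": -G / (H + lam)}
    best = None
    parent_score = G * G / (H + lam)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        xs, gs, hs = x[order, j], g[order], h[order]
        gl = np.cumsum(gs)[:-1]
        hl = np.cumsum(hs)[:-1]
        valid = xs[1:] != xs[:-1]
        if not valid.any():
            continue
        gain = 0.5 * (gl ** 2 / (hl + lam)
                      + (G - gl) ** 2 / (H - hl + lam)
                      - parent_score)
        gain[~valid] = -np.inf
        i = int(np.argmax(gain))
        if gain[i] > 1e-12 and (best is None or gain[i] > best[0] + 1e-15):
            thr = 0.5 * (xs[i] + xs[i + 1])
            best = (float(gain[i]), j, float(thr))
    if best is None:
        return {"leaf": -G / (H + lam)}
    _, j, thr = best
    mask = x[:, j] < thr
    return {
        "feature": j,
        "threshold": thr,
        "left": _fit_tree(x[mask], g[mask], h[mask], lam, depth - 1),
        "right": _fit_tree(x[~mask], g[~mask], h[~mask], lam, depth - 1),
    }


def _predict_tree(node, x):
    if "leaf" in node:
        return np.full(x.shape[0], node["leaf"])
    mask = x[:, node["feature"]] < node["threshold"]
    out = np.empty(x.shape[0])
    out[mask] = _predict_tree(node["left"], x[mask])
    out[~mask] = _predict_tree(node["right"], x[~mask])
    return out


@dataclass
class GBTEnsemble:
    """Additive model: ``score_k(x) = base_k + eta * sum_t tree_{t,k}(x)``."""

    config: GBTConfig
    num_classes: int
    n_features: int
    base_score: np.ndarray = None
    trees: list = field(default_factory=list)   # trees[t][k] = nested dict

    def to_json(self) -> dict:
        return {
            "config": {"eta": self.config.eta, "lam": self.config.lam,
                       "tau": self.config.tau, "max_depth": self.config.max_depth,
                       "seed": self.config.seed},
            "num_classes": self.num_classes,
            "n_features": self.n_features,
            "base_score": self.base_score.tolist(),
            "trees": self.trees,
        }

    @staticmethod
    def from_json(obj) -> "GBTEnsemble":
        return GBTEnsemble(config=GBTConfig(**obj["config"]),
                           num_classes=obj["num_classes"],
                           n_features=obj["n_features"],
                           base_score=np.asarray(obj["base_score"]),
                           trees=obj["trees"])


def fit_gbt(features: np.ndarray, labels: np.ndarray,
            config: GBTConfig | None = None) -> GBTEnsemble:
    """Fit the multiclass boosting ensemble on a samples x features matrix."""
    config = config or GBTConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2:
        raise ShapeError(f"expected samples x features, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("features must be finite")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("need at least two classes present in the labels")
    k = int(y.max()) + 1
    priors = np.bincount(y, minlength=k) / len(y)
    base = np.log(np.clip(priors, 1e-12, None))
    ens = GBTEnsemble(config=config, num_classes=k, n_features=x.shape[1],
                      base_score=base)
    scores = np.tile(base, (len(y), 1))
    for _ in range(config.tau):
        p = softmax(scores, axis=1)
        g, h = compute_grad_hess(p, y)
        round_trees = []
        for cls in range(k):
            tree = _fit_tree(x, g[:, cls], h[:, cls], config.lam, config.max_depth)
            round_trees.append(tree)
            scores[:, cls] += config.eta * _predict_tree(tree, x)
        ens.trees.append(round_trees)
    return ens


def decision_scores(ensemble: GBTEnsemble, features: np.ndarray,
                    n_rounds: int | None = None) -> np.ndarray:
    """Additive per-class raw scores, optionally truncated to ``n_rounds`` trees."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != ensemble.n_features:
        raise ShapeError(
            f"feature width {x.shape[-1] if x.ndim else '?'} does not match the "
            f"{ensemble.n_features} the ensemble was trained on")
    scores = np.tile(ensemble.base_score, (x.shape[0], 1))
    rounds = ensemble.trees if n_rounds is None else ensemble.trees[:n_rounds]
    for round_trees in rounds:
        for cls, tree in enumerate(round_trees):
            scores[:, cls] += ensemble.config.eta * _predict_tree(tree, x)
    return scores


def predict_gbt(ensemble: GBTEnsemble, features: np.ndarray) -> np.ndarray:
    """Class probabilities: softmax of the additive scores; rows sum to 1."""
    return softmax(decision_scores(ensemble, features), axis=1)


def training_logloss_curve(features, labels, config: GBTConfig) -> np.ndarray:
    """Training logloss after each boosting round (diagnostic helper)."""
    ens = fit_gbt(features, labels, config)
    y = np.asarray(labels, dtype=np.int64)
    losses = []
    for t in range(config.tau + 1):
        p = softmax(decision_scores(ens, features, n_rounds=t), axis=1)
        losses.append(float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1)).mean()))
    return np.asarray(losses)


# ----------------------------------------------------------------------------
# deep-feature input for the tree head
# ----------------------------------------------------------------------------

def deep_feature_input(model, backbones, batch, representation: str = "penultimate",
                       depthwise: bool = False, depthwise_kernels=None,
                       normalization: str = "unit") -> np.ndarray:
    """Feature matrix the tree head consumes, derived from the fusion model.

    ``penultimate`` returns the activations of the last hidden dense layer
    (width 128 for the basic head, 850 for the extended); ``probabilities``
    returns the softmax outputs. With ``depthwise=True`` each backbone's final
    feature map is passed through one depthwise convolution before pooling
    (identity kernels by default, which reproduce the standard path exactly).
    """
    from .backbones import extract, gap
    from .image import to_float
    from .nn import depthwise_conv2d

    if representation not in ("penultimate", "probabilities"):
        raise ParameterError(f"unknown representation {representation!r}")
    bb_a, bb_b = backbones
    pooled = []
    for i, bb in enumerate((bb_a, bb_b)):
        feats = []
        imgs = list(batch)
        for start in range(0, len(imgs), 8):
            xb = np.stack([to_float(img, normalization) for img in imgs[start:start + 8]])
            fmap = extract(bb, xb)
            if depthwise:
                kern = (identity_depthwise_kernel(fmap.shape[3])
                        if depthwise_kernels is None else depthwise_kernels[i])
                fmap = depthwise_conv2d(fmap, kern)
            feats.append(gap(fmap))
        pooled.append(np.concatenate(feats, axis=0))
    fa, fb = pooled
    if representation == "probabilities":
        return model.forward(fa, fb, training=False)
    return model.penultimate(fa, fb)
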