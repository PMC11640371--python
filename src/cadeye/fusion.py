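"""Feature-fusion classification heads and their training loop.

Pooled feature vectors from the two frozen backbones are fused (concatenation
by default; element-wise sum or product via a learned alignment transform) and
classified by a dense head trained with Adam on categorical cross-entropy:

- ``basic``    — fuse -> Dense(128, ReLU) -> Dense(num_classes, softmax);
- ``extended`` — fuse -> three dense blocks (per-channel depthwise transform,
  ReLU, batch normalization, additive skip) -> Dense(850, ReLU with batch
  norm) -> Dense(num_classes, softmax).

Because the blocks operate on pooled vectors (a 1x1 spatial grid), the
depthwise convolution degenerates to a per-feature affine transform and max
pooling to the identity, which keeps every stated component well defined on
vector inputs while preserving input/output widths for the skip connections.

Only head parameters are ever updated; the backbones stay frozen throughout
(checksummable before/after training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import Backbone, extract, gap
from .errors import DataError, ParameterError, ShapeError
from .image import to_float
from .nn import he_init, softmax

__all__ = [
    "BatchNormParams", "batch_norm", "fuse", "FusionModel", "build_fusion_model",
    "train", "train_on_features", "predict_proba", "predict_proba_features",
    "extract_pooled", "count_parameters",
]

_FUSION_MODES = ("concat", "sum", "product")
_HEAD_VARIANTS = ("basic", "extended")


# ----------------------------------------------------------------------------
# batch normalization
# ----------------------------------------------------------------------------

@dataclass
class BatchNormParams:
    """Learned scale/shift plus running batch statistics for one feature axis."""

    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = 1e-5
    momentum: float = 0.9
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    @staticmethod
    def create(n_features: int, epsilon: float = 1e-5) -> "BatchNormParams":
        if not epsilon > 0:
            raise ParameterError("epsilon must be positive")
        return BatchNormParams(
            gamma=np.ones(n_features, dtype=np.float32),
            beta=np.zeros(n_features, dtype=np.float32),
            epsilon=float(epsilon),
            running_mean=np.zeros(n_features, dtype=np.float32),
            running_var=np.ones(n_features, dtype=np.float32),
        )


def batch_norm(x: np.ndarray, params: BatchNormParams, training: bool) -> np.ndarray:
    """Normalize a (batch x features) array.

    Training mode standardizes by the mini-batch mean and (biased) variance
    and updates the running statistics in place; inference mode uses the
    running statistics. Output is ``gamma * x_hat + beta``.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 2:
        raise ShapeError(f"expected a batch x features array, got {x.shape}")
    if training:
        if x.shape[0] < 2:
            raise DataError("batch normalization in training mode needs batch size >= 2")
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        m = params.momentum
        params.running_mean[...] = m * params.running_mean + (1 - m) * mu
        params.running_var[...] = m * params.running_var + (1 - m) * var
    else:
        mu, var = params.running_mean, params.running_var
    x_hat = (x - mu) / np.sqrt(var + params.epsilon)
    return params.gamma * x_hat + params.beta


# ----------------------------------------------------------------------------
# fusion of pooled features
# ----------------------------------------------------------------------------

def fuse(a: np.ndarray, b: np.ndarray, mode: str = "concat",
         transform_a: np.ndarray | None = None,
         transform_b: np.ndarray | None = None) -> np.ndarray:
    """Combine two pooled feature batches.

    ``concat`` stacks widths; ``sum``/``product`` first map both inputs
    through linear alignment transforms (identity if omitted and the widths
    already agree) and then combine element-wise.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float32))
    b = np.atleast_2d(np.asarray(b, dtype=np.float32))
    if a.shape[0] != b.shape[0]:
        raise ShapeError(f"batch sizes differ: {a.shape[0]} vs {b.shape[0]}")
    if mode == "concat":
        return np.concatenate([a, b], axis=1)
    if mode not in _FUSION_MODES:
        raise ParameterError(f"unknown fusion mode {mode!r}")
    ta = a if transform_a is None else a @ transform_a
    tb = b if transform_b is None else b @ transform_b
    if ta.shape[1] != tb.shape[1]:
        raise ShapeError(
            f"widths {ta.shape[1]} vs {tb.shape[1]} are incompatible for {mode} "
            "fusion without an alignment transform")
    return ta + tb if mode == "sum" else ta * tb


# ----------------------------------------------------------------------------
# head layers (forward + backward)
# ----------------------------------------------------------------------------

class _Dense:
    def __init__(self, rng, din, dout, activation="linear"):
        self.w = he_init(rng, (din, dout), fan_in=din)
        self.b = np.zeros(dout, dtype=np.float32)
        self.activation = activation
        self._x = None
        self._y = None

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.w + self.b
        if self.activation == "relu":
            y = np.maximum(y, 0.0)
        self._y = y
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * (self._y > 0)
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class _BatchNorm:
    def __init__(self, n_features, epsilon=1e-5):
        self.p = BatchNormParams.create(n_features, epsilon)

    def forward(self, x, training=False):
        p = self.p
        if training:
            if x.shape[0] < 2:
                raise DataError("batch normalization needs batch size >= 2 in training")
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = p.momentum
            p.running_mean[...] = m * p.running_mean + (1 - m) * mu
            p.running_var[...] = m * p.running_var + (1 - m) * var
        else:
            mu, var = p.running_mean, p.running_var
        self._ivar = 1.0 / np.sqrt(var + p.epsilon)
        self._xhat = (x - mu) * self._ivar
        self._training = training
        return p.gamma * self._xhat + p.beta

    def backward(self, dy):
        p = self.p
        self.dgamma = (dy * self._xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * p.gamma
        if not self._training:
            return dxhat * self._ivar
        m = dy.shape[0]
        return (self._ivar / m) * (
            m * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))

    def params(self):
        return [self.p.gamma, self.p.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class _DenseBlock:
    """Vector-input dense block: depthwise transform -> ReLU -> batch norm,
    with an additive identity skip. Width-preserving by construction."""

    def __init__(self, rng, width, epsilon=1e-5):
        self.w = (1.0 + 0.1 * rng.standard_normal(width)).astype(np.float32)
        self.b = np.zeros(width, dtype=np.float32)
        self.bn = _BatchNorm(width, epsilon)

    def forward(self, x, training=False):
        self._x = x
        self._pre = self.w * x + self.b
        h = np.maximum(self._pre, 0.0)
        return self.bn.forward(h, training) + x

    def backward(self, dy):
        dh = self.bn.backward(dy)
        dpre = dh * (self._pre > 0)
        self.dw = (dpre * self._x).sum(axis=0)
        self.db = dpre.sum(axis=0)
        return dpre * self.w + dy

    def params(self):
        return [self.w, self.b] + self.bn.params()

    def grads(self):
        return [self.dw, self.db] + self.bn.grads()


# ----------------------------------------------------------------------------
# the fusion model
# ----------------------------------------------------------------------------

@dataclass
class FusionModel:
    fusion_mode: str
    head_variant: str
    num_classes: int
    channels_a: int
    channels_b: int
    transform_a: np.ndarray | None = None
    transform_b: np.ndarray | None = None
    layers: list = field(default_factory=list)
    output: _Dense = None
    seed: int = 0
    # fixed (non-trainable) input standardization, fitted on the training
    # features once; identity until then
    scaler_mean_a: np.ndarray = None
    scaler_std_a: np.ndarray = None
    scaler_mean_b: np.ndarray = None
    scaler_std_b: np.ndarray = None

    def fit_scaler(self, feats_a, feats_b) -> None:
        """Standardize head inputs by these features' mean/std from here on."""
        fa = np.asarray(feats_a, np.float32)
        fb = np.asarray(feats_b, np.float32)
        self.scaler_mean_a[...] = fa.mean(axis=0)
        self.scaler_std_a[...] = fa.std(axis=0) + 1e-6
        self.scaler_mean_b[...] = fb.mean(axis=0)
        self.scaler_std_b[...] = fb.std(axis=0) + 1e-6

    # -- forward ------------------------------------------------------------
    def _fused(self, fa, fb):
        fa = (np.asarray(fa, np.float32) - self.scaler_mean_a) / self.scaler_std_a
        fb = (np.asarray(fb, np.float32) - self.scaler_mean_b) / self.scaler_std_b
        self._fa, self._fb = fa, fb
        if self.fusion_mode == "concat":
            return np.concatenate([self._fa, self._fb], axis=1)
        self._ta = self._fa @ self.transform_a
        self._tb = self._fb @ self.transform_b
        return self._ta + self._tb if self.fusion_mode == "sum" else self._ta * self._tb

    def forward(self, fa, fb, training=False):
        """Class probabilities (softmax over logits) for pooled feature batches."""
        h = self._fused(fa, fb)
        for layer in self.layers:
            h = layer.forward(h, training)
        self._penultimate = h
        logits = self.output.forward(h, training)
        return softmax(logits, axis=1)

    def penultimate(self, fa, fb):
        """Activations of the last hidden layer (inference mode)."""
        self.forward(fa, fb, training=False)
        return self._penultimate.copy()

    # -- backward -----------------------------------------------------------
    def backward_from_logits(self, dlogits):
        dh = self.output.backward(dlogits)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        # dh is the gradient w.r.t. the fused vector; push through fusion
        if self.fusion_mode == "concat":
            dfa = dh[:, :self.channels_a]
            dfb = dh[:, self.channels_a:]
            self.dtransform_a = self.dtransform_b = None
        elif self.fusion_mode == "sum":
            self.dtransform_a = self._fa.T @ dh
            self.dtransform_b = self._fb.T @ dh
            dfa = dh @ self.transform_a.T
            dfb = dh @ self.transform_b.T
        else:  # product
            da_t = dh * self._tb
            db_t = dh * self._ta
            self.dtransform_a = self._fa.T @ da_t
            self.dtransform_b = self._fb.T @ db_t
            dfa = da_t @ self.transform_a.T
            dfb = db_t @ self.transform_b.T
        # chain through the fixed input standardization back to raw features
        return dfa / self.scaler_std_a, dfb / self.scaler_std_b

    def input_gradient(self, fa, fb, target: int):
        """d(logit of ``target``)/d(pooled inputs), inference mode; used by Grad-CAM."""
        if not 0 <= int(target) < self.num_classes:
            raise ParameterError(f"class index {target} out of range")
        self.forward(fa, fb, training=False)
        n = np.asarray(fa).shape[0] if np.asarray(fa).ndim == 2 else 1
        dlogits = np.zeros((n, self.num_classes), dtype=np.float32)
        dlogits[:, int(target)] = 1.0
        return self.backward_from_logits(dlogits)

    # -- parameters ----------------------------------------------------------
    def params(self):
        out = []
        if self.fusion_mode != "concat":
            out += [self.transform_a, self.transform_b]
        for layer in self.layers:
            out += layer.params()
        out += self.output.params()
        return out

    def grads(self):
        out = []
        if self.fusion_mode != "concat":
            out += [self.dtransform_a, self.dtransform_b]
        for layer in self.layers:
            out += layer.grads()
        out += self.output.grads()
        return out


def count_parameters(model: FusionModel) -> int:
    return int(sum(p.size for p in model.params()))


def build_fusion_model(channels_a: int, channels_b: int, num_classes: int = 5,
                       variant: str = "basic", fusion_mode: str = "concat",
                       seed: int = 0) -> FusionModel:
    """Build a seeded fusion head.

    Basic: Dense(128, ReLU) then Dense(num_classes); extended: three
    width-preserving dense blocks, Dense(850) with batch norm and ReLU, then
    Dense(num_classes). Softmax is applied in :meth:`FusionModel.forward`.
    """
    if variant not in _HEAD_VARIANTS:
        raise ParameterError(f"unknown head variant {variant!r}; expected {_HEAD_VARIANTS}")
    if fusion_mode not in _FUSION_MODES:
        raise ParameterError(f"unknown fusion mode {fusion_mode!r}")
    if channels_a < 1 or channels_b < 1:
        raise ParameterError("channel counts must be >= 1")
    if num_classes < 2:
        raise ParameterError("need at least two classes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7]))
    model = FusionModel(fusion_mode=fusion_mode, head_variant=variant,
                        num_classes=int(num_classes), channels_a=int(channels_a),
                        channels_b=int(channels_b), seed=int(seed),
                        scaler_mean_a=np.zeros(channels_a, dtype=np.float32),
                        scaler_std_a=np.ones(channels_a, dtype=np.float32),
                        scaler_mean_b=np.zeros(channels_b, dtype=np.float32),
                        scaler_std_b=np.ones(channels_b, dtype=np.float32))
    if fusion_mode == "concat":
        fused_dim = channels_a + channels_b
    else:
        fused_dim = max(channels_a, channels_b)
        model.transform_a = he_init(rng, (channels_a, fused_dim), fan_in=channels_a)
        model.transform_b = he_init(rng, (channels_b, fused_dim), fan_in=channels_b)
    if variant == "basic":
        model.layers = [_Dense(rng, fused_dim, 128, activation="relu")]
        model.output = _Dense(rng, 128, num_classes)
    else:
        blocks = [_DenseBlock(rng, fused_dim) for _ in range(3)]
        dense850 = _Dense(rng, fused_dim, 850)
        bn850 = _BatchNorm(850)
        relu850 = _ReLU()
        model.layers = blocks + [dense850, bn850, relu850]
        model.output = _Dense(rng, 850, num_classes)
    return model


class _ReLU:
    def forward(self, x, training=False):
        self._y = np.maximum(x, 0.0)
        return self._y

    def backward(self, dy):
        return dy * (self._y > 0)

    def params(self):
        return []

    def grads(self):
        return []


# ----------------------------------------------------------------------------
# training
# ----------------------------------------------------------------------------

def _cross_entropy(p, y_onehot):
    return float(-(y_onehot * np.log(np.clip(p, 1e-12, 1.0))).sum() / p.shape[0])


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stratified_split(labels, fraction, rng):
    labels = np.asarray(labels)
    val_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_val = int(round(fraction * len(idx)))
        val_idx.extend(rng.permutation(idx)[:n_val].tolist())
    val = np.zeros(len(labels), dtype=bool)
    val[val_idx] = True
    return ~val, val


def train_on_features(model: FusionModel, feats_a, feats_b, labels, epochs: int,
                      seed: int = 0, lr: float = 3e-3, batch_size: int = 32,
                      val_fraction: float = 0.1, lr_schedule: str = "cosine",
                      restore_best: bool = True):
    """Adam training of the head on precomputed pooled features.

    The learning rate follows a cosine decay over the epoch budget
    (``lr_schedule="constant"`` disables it) and, when a validation split
    exists, the parameters of the best-validation-accuracy epoch are restored
    at the end (``restore_best=False`` keeps the last epoch instead).

    Returns a history: one dict per epoch with train/validation loss and
    accuracy. Zero epochs returns an empty history and touches nothing.
    """
    fa = np.asarray(feats_a, dtype=np.float32)
    fb = np.asarray(feats_b, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if len(y) == 0:
        raise DataError("empty training split")
    if epochs == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11]))
    k = model.num_classes
    model.fit_scaler(fa, fb)
    train_mask, val_mask = _stratified_split(y, val_fraction, rng)
    if not val_mask.any():
        train_mask = np.ones(len(y), dtype=bool)
    fa_tr, fb_tr, y_tr = fa[train_mask], fb[train_mask], y[train_mask]
    fa_va, fb_va, y_va = fa[val_mask], fb[val_mask], y[val_mask]
    onehot = np.eye(k, dtype=np.float32)
    opt = _Adam(model.params(), lr=lr)
    history = []
    n = len(y_tr)
    best = (-1.0, None)
    for epoch in range(int(epochs)):
        if lr_schedule == "cosine":
            opt.lr = lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(int(epochs), 1)))
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs >= 2; remainder folds into next epoch
            yb = onehot[y_tr[idx]]
            p = model.forward(fa_tr[idx], fb_tr[idx], training=True)
            loss = _cross_entropy(p, yb)
            dlogits = (p - yb) / len(idx)
            model.backward_from_logits(dlogits)
            opt.step(model.grads())
            ep_loss += loss * len(idx)
            ep_correct += int((p.argmax(axis=1) == y_tr[idx]).sum())
        rec = {"epoch": epoch, "train_loss": ep_loss / n, "train_acc": ep_correct / n}
        if val_mask.any():
            pv = model.forward(fa_va, fb_va, training=False)
            rec["val_loss"] = _cross_entropy(pv, onehot[y_va])
            rec["val_acc"] = float((pv.argmax(axis=1) == y_va).mean())
            if restore_best and rec["val_acc"] > best[0]:
                best = (rec["val_acc"], [a.copy() for a in _state_arrays(model)])
        history.append(rec)
    if restore_best and best[1] is not None:
        for arr, saved in zip(_state_arrays(model), best[1]):
            arr[...] = saved
    return history


def extract_pooled(backbone: Backbone, images, batch_size: int = 8,
                   normalization: str = "unit") -> np.ndarray:
    """Pooled features for a list/array of uint8 images, batched for memory."""
    feats = []
    for start in range(0, len(images), batch_size):
        batch = np.stack([to_float(img, normalization) for img in images[start:start + batch_size]])
        feats.append(gap(extract(backbone, batch)))
    return np.concatenate(feats, axis=0)


def train(model: FusionModel, backbones, manifest, epochs: int, seed: int = 0,
          lr: float = 3e-3, batch_size: int = 32, val_fraction: float = 0.1,
          normalization: str = "unit"):
    """Train the head from a dataset manifest (train split only).

    Images are loaded from the manifest, normalized, passed through both
    frozen backbones, pooled, and the head is fitted on the cached features.
    """
    from .image import load_image
    from .synthetic import CLASS_LABELS

    df = manifest.records
    train_df = df[df["split"] == "train"]
    if train_df.empty:
        raise DataError("manifest has no training records")
    label_names = sorted(train_df["label"].unique(),
                         key=lambda s: CLASS_LABELS.index(s) if s in CLASS_LABELS else 99)
    label_to_idx = {s: i for i, s in enumerate(label_names)}
    images = [load_image(p) for p in train_df["path"]]
    y = np.array([label_to_idx[s] for s in train_df["label"]])
    bb_a, bb_b = backbones
    fa = extract_pooled(bb_a, images, normalization=normalization)
    fb = extract_pooled(bb_b, images, normalization=normalization)
    return train_on_features(model, fa, fb, y, epochs, seed=seed, lr=lr,
                             batch_size=batch_size, val_fraction=val_fraction)


def _state_arrays(model: FusionModel):
    """Trainable parameters, scaler constants and batch-norm running
    statistics, in a fixed order."""
    arrays = list(model.params())
    arrays += [model.scaler_mean_a, model.scaler_std_a,
               model.scaler_mean_b, model.scaler_std_b]
    for layer in model.layers:
        bns = []
        if isinstance(layer, _BatchNorm):
            bns = [layer]
        elif isinstance(layer, _DenseBlock):
            bns = [layer.bn]
        for bn in bns:
            arrays += [bn.p.running_mean, bn.p.running_var]
    return arrays


def save_fusion_model(model: FusionModel, path) -> None:
    """Portable checkpoint: JSON architecture header + npz weight archive."""
    import json
    header = {
        "fusion_mode": model.fusion_mode,
        "head_variant": model.head_variant,
        "num_classes": model.num_classes,
        "channels_a": model.channels_a,
        "channels_b": model.channels_b,
        "seed": model.seed,
    }
    arrays = _state_arrays(model)
    header["n_arrays"] = len(arrays)
    with open(str(path) + ".json", "w") as fh:
        json.dump(header, fh, indent=2)
    np.savez(str(path) + ".npz", *arrays)


def load_fusion_model(path) -> FusionModel:
    import json
    with open(str(path) + ".json") as fh:
        header = json.load(fh)
    model = build_fusion_model(header["channels_a"], header["channels_b"],
                               header["num_classes"], header["head_variant"],
                               header["fusion_mode"], header["seed"])
    archive = np.load(str(path) + ".npz")
    for i, arr in enumerate(_state_arrays(model)):
        arr[...] = archive[f"arr_{i}"]
    return model


def predict_proba_features(model: FusionModel, feats_a, feats_b) -> np.ndarray:
    return model.forward(feats_a, feats_b, training=False)


def predict_proba(model: FusionModel, backbones, batch,
                  normalization: str = "unit") -> np.ndarray:
    """Class probabilities for a batch of uint8 images; rows sum to 1."""
    bb_a, bb_b = backbones
    fa = extract_pooled(bb_a, list(batch), normalization=normalization)
    fb = extract_pooled(bb_b, list(batch), normalization=normalization)
    return predict_proba_features(model, fa, fb)
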