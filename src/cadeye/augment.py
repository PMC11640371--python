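"""Training-set augmentation and class balancing.

The augmentation scheme follows the AutoAugment convention: a policy is an
ordered list of sub-policies, each sub-policy a short sequence of
``(operation, probability, magnitude)`` triples with magnitudes on a 0..9
scale mapping linearly onto bounded geometric/photometric ranges. One
sub-policy is drawn uniformly per augmented image.

Class balancing is oversampling-with-augmentation: augmented copies of
minority-class training images are added until every training class matches
the largest one. Originals are never deleted and the test split is never
touched — augmentation applies to the training data only, so evaluation
remains untouched by synthetic variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance

from .errors import DataError, ParameterError
from .image import validate_rgb
from .synthetic import DatasetManifest

__all__ = [
    "OPERATIONS",
    "AugmentPolicy",
    "build_policy",
    "default_policy",
    "augment_image",
    "balance_training_set",
]

OPERATIONS = (
    "rotate", "translate_x", "translate_y", "shear_x", "shear_y",
    "flip_horizontal", "brightness", "contrast", "color", "sharpness",
    "cutout", "crop_resize",
)

# magnitude level 9 maps to these maxima (linear in the level)
_MAX_ROTATE_DEG = 15.0
_MAX_TRANSLATE_FRAC = 0.10
_MAX_SHEAR_DEG = 8.0
_MAX_ENHANCE_DELTA = 0.20   # brightness/contrast/color/sharpness factor = 1 +/- delta
_MAX_CUTOUT_AREA = 0.10
_MAX_CROP_AREA_LOSS = 0.15


@dataclass(frozen=True)
class AugmentPolicy:
    """Validated list of sub-policies; empty list is the identity augmenter."""

    sub_policies: tuple = ()

    def is_identity(self) -> bool:
        return len(self.sub_policies) == 0


def build_policy(config=None) -> AugmentPolicy:
    """Validate a policy description (list of lists of ``(op, prob, level)``).

    ``None`` returns the package default policy; ``[]`` builds the identity
    augmenter.
    """
    if config is None:
        return default_policy()
    subs = []
    for sub in config:
        triples = []
        for op, prob, level in sub:
            if op not in OPERATIONS:
                raise ParameterError(f"unknown augmentation operation {op!r}")
            if not 0.0 <= float(prob) <= 1.0:
                raise ParameterError(f"probability must lie in [0,1], got {prob}")
            if not 0 <= int(level) <= 9:
                raise ParameterError(f"magnitude level must lie in 0..9, got {level}")
            triples.append((op, float(prob), int(level)))
        subs.append(tuple(triples))
    return AugmentPolicy(sub_policies=tuple(subs))


def default_policy() -> AugmentPolicy:
    """Fixed five-sub-policy default: mild rotations, shifts, shears,
    photometric jitter, horizontal flips and cutout."""
    return build_policy([
        [("rotate", 0.8, 6), ("brightness", 0.4, 5)],
        [("translate_x", 0.6, 5), ("translate_y", 0.6, 5)],
        [("shear_x", 0.5, 5), ("contrast", 0.5, 5)],
        [("flip_horizontal", 0.5, 0), ("sharpness", 0.3, 5)],
        [("cutout", 0.5, 5), ("color", 0.3, 5)],
    ])


def _signed(rng: np.random.Generator, value: float) -> float:
    return float(rng.choice([-1.0, 1.0])) * value


def _apply_op(img: np.ndarray, op: str, level: int, rng: np.random.Generator) -> np.ndarray:
    frac = level / 9.0
    h, w = img.shape[:2]
    pil = Image.fromarray(img)
    if op == "rotate":
        angle = _signed(rng, _MAX_ROTATE_DEG * frac)
        out = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    elif op in ("translate_x", "translate_y"):
        shift = _signed(rng, _MAX_TRANSLATE_FRAC * frac) * (w if op == "translate_x" else h)
        mat = (1, 0, shift, 0, 1, 0) if op == "translate_x" else (1, 0, 0, 0, 1, shift)
        out = pil.transform(pil.size, Image.AFFINE, mat, resample=Image.BILINEAR,
                            fillcolor=(0, 0, 0))
    elif op in ("shear_x", "shear_y"):
        s = _signed(rng, math.tan(math.radians(_MAX_SHEAR_DEG)) * frac)
        mat = (1, s, 0, 0, 1, 0) if op == "shear_x" else (1, 0, 0, s, 1, 0)
        out = pil.transform(pil.size, Image.AFFINE, mat, resample=Image.BILINEAR,
                            fillcolor=(0, 0, 0))
    elif op == "flip_horizontal":
        out = pil.transpose(Image.FLIP_LEFT_RIGHT)
    elif op in ("brightness", "contrast", "color", "sharpness"):
        enhancer = {
            "brightness": ImageEnhance.Brightness,
            "contrast": ImageEnhance.Contrast,
            "color": ImageEnhance.Color,
            "sharpness": ImageEnhance.Sharpness,
        }[op](pil)
        out = enhancer.enhance(1.0 + _signed(rng, _MAX_ENHANCE_DELTA * frac))
    elif op == "cutout":
        arr = img.copy()
        side = int(round(math.sqrt(_MAX_CUTOUT_AREA * frac) * min(h, w)))
        if side > 0:
            y = int(rng.integers(0, max(h - side, 1)))
            x = int(rng.integers(0, max(w - side, 1)))
            arr[y:y + side, x:x + side] = 0
        return arr
    elif op == "crop_resize":
        keep = 1.0 - _MAX_CROP_AREA_LOSS * frac
        ch, cw = max(int(h * math.sqrt(keep)), 1), max(int(w * math.sqrt(keep)), 1)
        y = int(rng.integers(0, h - ch + 1))
        x = int(rng.integers(0, w - cw + 1))
        out = pil.crop((x, y, x + cw, y + ch)).resize((w, h), Image.BILINEAR)
    else:  # pragma: no cover - guarded by build_policy
        raise ParameterError(f"unknown operation {op!r}")
    return np.asarray(out)


def augment_image(img: np.ndarray, policy: AugmentPolicy, rng_seed: int) -> np.ndarray:
    """Apply one randomly chosen sub-policy; deterministic given the seed."""
    img = validate_rgb(img)
    if policy.is_identity():
        return img
    rng = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)
    sub = policy.sub_policies[int(rng.integers(len(policy.sub_policies)))]
    out = img
    for op, prob, level in sub:
        if rng.random() < prob:
            out = _apply_op(out, op, level, rng)
    return validate_rgb(out)


def balance_training_set(manifest: DatasetManifest, policy: AugmentPolicy,
                         rng_seed: int, out_dir=None) -> DatasetManifest:
    """Oversample minority training classes with augmented copies.

    Every training class is brought up to the size of the largest training
    class by augmenting cyclically chosen originals of that class; new files
    are written beside the originals (or under ``out_dir``) and appended to
    the returned manifest. Test records are passed through bit-identically.
    """
    from .image import load_image, save_image

    df = manifest.records
    train = df[df["split"] == "train"]
    test = df[df["split"] == "test"]
    counts = train["label"].value_counts()
    if counts.empty or (counts == 0).any():
        raise DataError("every class needs at least one training image to balance")
    target = int(counts.max())
    new_rows = []
    for label, n in sorted(counts.items()):
        deficit = target - int(n)
        if deficit == 0:
            continue
        originals = train[train["label"] == label]["path"].tolist()
        for j in range(deficit):
            src = originals[j % len(originals)]
            seed = np.random.SeedSequence(
                [int(rng_seed) & 0x7FFFFFFF, CLASS_INDEX[label], j]).generate_state(1)[0]
            aug = augment_image(load_image(src), policy, int(seed) & 0x7FFFFFFF)
            src_path = Path(src)
            dest_dir = Path(out_dir) if out_dir is not None else src_path.parent
            dest_dir.mkdir(parents=True, exist_ok=True)
            dest = dest_dir / f"{src_path.stem}_aug{j:04d}.png"
            save_image(aug, dest)
            new_rows.append({"path": str(dest), "label": label,
                             "split": "train", "source": "augmented"})
    out = pd.concat([train, pd.DataFrame(new_rows,
                                         columns=["path", "label", "split", "source"]),
                     test], ignore_index=True)
    return DatasetManifest(records=out, source_table=manifest.source_table,
                           inconsistent=manifest.inconsistent,
                           inconsistency_notes=list(manifest.inconsistency_notes))


# label -> stable integer for seed derivation (covers arbitrary user labels too)
class _ClassIndex(dict):
    def __missing__(self, key):
        # stable hash independent of PYTHONHASHSEED
        val = sum((i + 1) * b for i, b in enumerate(str(key).encode())) % 1000
        self[key] = val
        return val


CLASS_INDEX = _ClassIndex()
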