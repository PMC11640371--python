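"""Grad-CAM class-activation heatmaps and overlay rendering.

Standard Grad-CAM over a backbone's final convolutional stage: channel
weights are the spatial mean of the class-score gradient with respect to the
feature map; the map is the ReLU of the weighted channel sum, upsampled to
the input size and min-max normalized to [0, 1].

Because the classifier consumes globally average-pooled features, the
gradient of a class logit with respect to feature-map position ``(c, i, j)``
is ``d logit / d pooled_c / (H' W')`` — spatially constant — so the channel
weights come directly from the head's analytic input gradient. Heatmaps are
a diagnostic output; the classification path never consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .backbones import extract, gap
from .errors import ParameterError, ShapeError
from .fluorescence import hot_lut
from .image import to_float, validate_rgb

__all__ = ["Heatmap", "gradcam", "overlay"]


@dataclass
class Heatmap:
    """Spatial saliency grid in [0, 1] for one target class."""

    values: np.ndarray
    target_class: str | int

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ShapeError(f"heatmap must be a 2-D grid, got {v.shape}")


def _cam_from(fmap: np.ndarray, pooled_grad: np.ndarray) -> np.ndarray:
    """ReLU of the channel sum weighted by spatially averaged gradients."""
    hprime, wprime = fmap.shape[1:3]
    weights = pooled_grad / (hprime * wprime)       # alpha_c, spatial mean of d score/d A_c
    cam = np.einsum("nhwc,nc->nhw", fmap, weights)
    return np.maximum(cam, 0.0)


def _normalize_upsample(cam: np.ndarray, out_shape) -> np.ndarray:
    h, w = out_shape
    zoom = (h / cam.shape[0], w / cam.shape[1])
    up = ndimage.zoom(cam, zoom, order=1, mode="nearest")[:h, :w]
    peak = up.max()
    if peak <= 0.0:
        return np.zeros((h, w), dtype=np.float64)
    return up / peak


def gradcam(model, backbones, img: np.ndarray, target, class_names=None,
            which: str = "combined", normalization: str = "unit") -> Heatmap:
    """Grad-CAM heatmap for one image and one target class.

    ``which`` selects the feature source: ``"a"``/``"b"`` for either
    backbone's final conv stage, or ``"combined"`` for the average of both
    maps. ``target`` may be a class index or a name resolvable through
    ``class_names``.
    """
    img = validate_rgb(img)
    if isinstance(target, str):
        if class_names is None or target not in class_names:
            raise ParameterError(f"cannot resolve class name {target!r}")
        target_idx = list(class_names).index(target)
    else:
        target_idx = int(target)
    if not 0 <= target_idx < model.num_classes:
        raise ParameterError(f"class index {target_idx} out of range")
    if which not in ("a", "b", "combined"):
        raise ParameterError(f"which must be 'a', 'b' or 'combined', got {which!r}")

    bb_a, bb_b = backbones
    x = to_float(img, normalization)[None]
    fmap_a = extract(bb_a, x)
    fmap_b = extract(bb_b, x)
    dfa, dfb = model.input_gradient(gap(fmap_a), gap(fmap_b), target_idx)
    out_shape = img.shape[:2]
    if which == "a":
        cam = _normalize_upsample(_cam_from(fmap_a, dfa)[0], out_shape)
    elif which == "b":
        cam = _normalize_upsample(_cam_from(fmap_b, dfb)[0], out_shape)
    else:
        cam_a = _normalize_upsample(_cam_from(fmap_a, dfa)[0], out_shape)
        cam_b = _normalize_upsample(_cam_from(fmap_b, dfb)[0], out_shape)
        cam = (cam_a + cam_b) / 2.0
        peak = cam.max()
        if peak > 0:
            cam = cam / peak
    return Heatmap(values=cam, target_class=target)


def overlay(img: np.ndarray, heatmap: Heatmap, opacity: float = 0.5) -> np.ndarray:
    """Alpha-blend a HOT-colormapped heatmap over the image.

    ``opacity`` 0 returns the original image, 1 the pure colormapped map.
    """
    if not 0.0 <= opacity <= 1.0:
        raise ParameterError(f"opacity must lie in [0, 1], got {opacity}")
    img = validate_rgb(img)
    values = np.asarray(heatmap.values, dtype=np.float64)
    if values.shape != img.shape[:2]:
        raise ShapeError(
            f"heatmap shape {values.shape} does not match image {img.shape[:2]}")
    lut = hot_lut()
    colored = lut[np.clip(np.floor(values * 255.0 + 0.5), 0, 255).astype(np.uint8)]
    blend = (1.0 - opacity) * img.astype(np.float64) + opacity * colored.astype(np.float64)
    return np.clip(np.floor(blend + 0.5), 0, 255).astype(np.uint8)
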