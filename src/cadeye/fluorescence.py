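"""Fluorescence-simulation preprocessing for fundus photographs.

Fluorescein angiography highlights retinal vasculature and leakage as bright
green structure on a dark field. This module approximates that visual emphasis
with deterministic channel arithmetic on an ordinary color fundus photo:

1. split the image into R, G, B channels;
2. amplify the green channel, ``G' = alpha * G`` (``alpha`` defaults to 2.0),
   clipped to the 8-bit range;
3. re-merge as ``(R, G', B)``;
4. optionally zero the blue channel so the green emphasis dominates;
5. optionally map the processed green channel through a HOT lookup table
   (black -> red -> yellow -> white) for visualization.

The transform is purely per-pixel and bit-reproducible; it is the default
preprocessing step of the classification pipeline (without the colormap, which
is a visualization-only branch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeError
from .image import validate_rgb

__all__ = [
    "FluorescenceConfig",
    "split_channels",
    "enhance_green",
    "merge_channels",
    "suppress_blue",
    "apply_colormap",
    "fluorescence_simulate",
    "hot_lut",
]

_ALLOWED_COLORMAPS = ("none", "hot")


@dataclass(frozen=True)
class FluorescenceConfig:
    """Parameters of the fluorescence simulation.

    Attributes
    ----------
    alpha : float
        Green-channel scaling factor, must be > 0. Default 2.0.
    suppress_blue : bool
        Zero the blue channel after green enhancement. Default True.
    colormap : str
        ``"none"`` (classification path) or ``"hot"`` (visualization).
    """

    alpha: float = 2.0
    suppress_blue: bool = True
    colormap: str = "none"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if str(self.colormap).lower() not in _ALLOWED_COLORMAPS:
            raise ParameterError(
                f"colormap must be one of {_ALLOWED_COLORMAPS}, got {self.colormap!r}"
            )


def split_channels(img: np.ndarray):
    """Separate an RGB image into its three single-channel intensity grids."""
    img = validate_rgb(img)
    return img[..., 0].copy(), img[..., 1].copy(), img[..., 2].copy()


def enhance_green(channel_g: np.ndarray, alpha: float) -> np.ndarray:
    """Scale a green channel by ``alpha`` with round-half-away-from-zero, clipped to 255."""
    if not alpha > 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    g = np.asarray(channel_g)
    if g.size and (g.min() < 0 or g.max() > 255):
        raise ValueError("channel intensities must lie in [0, 255]")
    scaled = np.floor(g.astype(np.float64) * float(alpha) + 0.5)
    return np.clip(scaled, 0, 255).astype(np.uint8)


def merge_channels(channel_r, channel_g, channel_b) -> np.ndarray:
    """Stack three equal-shaped grids back into an ``(R, G, B)`` image."""
    r, g, b = (np.asarray(c) for c in (channel_r, channel_g, channel_b))
    if not (r.shape == g.shape == b.shape):
        raise ShapeError(f"channel shapes differ: {r.shape}, {g.shape}, {b.shape}")
    if r.ndim != 2:
        raise ShapeError(f"channels must be 2-D grids, got {r.ndim} axes")
    return np.stack([r, g, b], axis=-1).astype(np.uint8)


def suppress_blue(img: np.ndarray) -> np.ndarray:
    """Return a copy of the image with the blue channel set to 0."""
    img = validate_rgb(img)
    out = img.copy()
    out[..., 2] = 0
    return out


def hot_lut() -> np.ndarray:
    """256-entry HOT lookup table (uint8, shape ``(256, 3)``).

    Intensity ramps black -> red -> yellow -> white in equal thirds; entries 0
    and 255 map exactly to black and white. Computed in-process so outputs are
    bit-reproducible without any plotting dependency.
    """
    t = np.arange(256) / 255.0
    r = np.clip(3.0 * t, 0.0, 1.0)
    g = np.clip(3.0 * t - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * t - 2.0, 0.0, 1.0)
    return np.clip(np.floor(np.stack([r, g, b], axis=1) * 255.0 + 0.5), 0, 255).astype(np.uint8)


_HOT = hot_lut()


def apply_colormap(img: np.ndarray, colormap: str) -> np.ndarray:
    """Map the green channel of ``img`` through a named 256-entry lookup table."""
    name = str(colormap).lower()
    if name == "hot":
        img = validate_rgb(img)
        return _HOT[img[..., 1]]
    raise ParameterError(f"unknown colormap {colormap!r}")


def fluorescence_simulate(img: np.ndarray, cfg: FluorescenceConfig | None = None) -> np.ndarray:
    """Run the full fluorescence simulation on one image.

    Steps: split -> green enhancement -> merge -> (blue suppression) ->
    (colormap). Deterministic; preserves spatial shape.
    """
    cfg = cfg or FluorescenceConfig()
    r, g, b = split_channels(img)
    out = merge_channels(r, enhance_green(g, cfg.alpha), b)
    if cfg.suppress_blue:
        out = suppress_blue(out)
    if str(cfg.colormap).lower() == "hot":
        out = apply_colormap(out, "hot")
    assert out.min() >= 0 and out.max() <= 255
    return out
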