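"""8-bit RGB image container conventions and raster I/O.

Images are ``numpy`` arrays of shape ``(height, width, 3)`` with dtype
``uint8`` — rows are the vertical axis everywhere in the package. Sizes given
as ``W x H`` pairs (the convention of camera spec sheets, e.g. ``700 x 600``)
are converted to ``(rows=H, cols=W)`` at the array boundary.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .errors import ShapeError

__all__ = ["validate_rgb", "load_image", "save_image", "resize", "to_float", "from_float"]


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check the RGB image contract and return the array unchanged.

    Raises
    ------
    ShapeError
        If the array is not ``H x W x 3`` with ``H, W >= 1``.
    ValueError
        If intensities fall outside ``[0, 255]``.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ShapeError(f"image must be at least 1 x 1, got {arr.shape[:2]}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or np.issubdtype(arr.dtype, np.integer):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        else:
            raise ShapeError(f"unsupported dtype {arr.dtype}")
    return arr


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG file as an ``H x W x 3`` uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(img: np.ndarray, path) -> None:
    # low PNG compression: deterministic bytes, much faster on large rasters
    Image.fromarray(validate_rgb(img)).save(path, compress_level=1)


def resize(img: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize to ``width x height`` pixels (output shape ``(height, width, 3)``)."""
    img = validate_rgb(img)
    out = Image.fromarray(img).resize((int(width), int(height)), Image.BILINEAR)
    return np.asarray(out)


def to_float(img: np.ndarray, mode: str = "unit") -> np.ndarray:
    """Normalize an 8-bit image to float32.

    ``unit`` scales each channel to [0, 1]; ``zscore`` standardizes each
    channel by its own mean and standard deviation (per image).
    """
    img = validate_rgb(img).astype(np.float32)
    if mode == "unit":
        return img / 255.0
    if mode == "zscore":
        mu = img.mean(axis=(0, 1), keepdims=True)
        sd = img.std(axis=(0, 1), keepdims=True)
        return (img - mu) / np.maximum(sd, 1e-6)
    raise ValueError(f"unknown normalization mode {mode!r}")


def from_float(img: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(img * 255.0 + 0.5), 0, 255).astype(np.uint8)
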