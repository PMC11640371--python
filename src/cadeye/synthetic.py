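"""Seeded synthetic fundus-image generator and dataset manifests.

Real multi-disease fundus corpora are mostly private or license-restricted, so
the pipeline ships a generator that draws fundus-like images with
class-discriminative structure for five classes:

- ``normal``              — retinal field, optic disc, vessel tree, no lesions;
- ``diabetic_retinopathy``— dark-red dot hemorrhages and bright yellow exudates;
- ``hypertensive_retinopathy`` — thinned vessels and soft cotton-wool patches;
- ``glaucoma``            — enlarged bright optic cup (cup/disc area ratio > 0.6);
- ``contrast``            — global haze blending the image toward mid-gray
  (the cataract-like "contrast" disorder class).

Rendering uses simple parametric shapes (soft disks, Gaussian blobs,
random-walk vessel trees); no photorealism is attempted — downstream stages
only need visually separable classes. Raw images are generated at
1125 x 1264 px (width x height) and later resized by the pipeline to
700 x 600 px, exercising the same geometry path real data would take.

The module also packages the published multi-source dataset composition table
(eight sources x five classes, 65,871 images in total) as
:func:`table3_manifest`, reproducing the printed cells verbatim — including a
documented internal inconsistency — for bookkeeping and audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, ParameterError
from .image import save_image

__all__ = [
    "CLASS_LABELS",
    "GeneratorParams",
    "DatasetManifest",
    "generate_image",
    "generate_dataset",
    "table3_manifest",
]

CLASS_LABELS = (
    "normal",
    "diabetic_retinopathy",
    "hypertensive_retinopathy",
    "glaucoma",
    "contrast",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic generator.

    Sizes follow the raw acquisition resolution of the emulated corpus
    (1125 px wide, 1264 px tall). Lesion knobs control how many blobs are
    drawn per image and how strong each class signature is; defaults were
    chosen once to give clearly separable classes without photorealism.
    """

    raw_height: int = 1264
    raw_width: int = 1125
    n_per_class: int = 100
    seed: int = 0
    test_fraction: float = 0.15
    # class-signature knobs
    dr_dot_count: tuple[int, int] = (25, 45)
    dr_exudate_count: tuple[int, int] = (8, 16)
    hr_patch_count: tuple[int, int] = (5, 9)
    vessel_width_normal: int = 4
    vessel_width_hr: int = 1
    cup_disc_area_ratio: float = 0.72
    normal_cup_area_ratio: float = 0.2
    haze_strength: float = 0.55

    def __post_init__(self) -> None:
        if self.raw_height < 64 or self.raw_width < 64:
            raise ParameterError("raw dimensions must be at least 64 px")
        if self.n_per_class < 0:
            raise ParameterError("per-class counts must be nonnegative")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ParameterError("test_fraction must lie in [0, 1)")


@dataclass
class DatasetManifest:
    """Records of generated (or user-supplied) images plus bookkeeping tables.

    ``records`` has columns ``path,label,split,source``; ``source_table`` is a
    per-source count table (rows = sources, columns = classes + Total), used
    for the packaged published composition table. ``inconsistent`` flags a
    source table whose printed cells do not add up.
    """

    records: pd.DataFrame
    source_table: pd.DataFrame | None = None
    inconsistent: bool = False
    inconsistency_notes: list[str] = field(default_factory=list)

    def class_counts(self, split: str | None = None) -> pd.Series:
        df = self.records
        if split is not None:
            df = df[df["split"] == split]
        return df["label"].value_counts()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "DatasetManifest":
        return DatasetManifest(records=pd.read_csv(path))


# ----------------------------------------------------------------------------
# rendering primitives
# ----------------------------------------------------------------------------

def _soft_disk(canvas: np.ndarray, cy: float, cx: float, radius: float,
               color, alpha: float = 1.0, softness: float = 0.25) -> None:
    """Alpha-blend a disk with a soft rim onto a float RGB canvas, in place."""
    h, w = canvas.shape[:2]
    r_out = radius * (1.0 + softness)
    y0, y1 = max(0, int(cy - r_out) - 1), min(h, int(cy + r_out) + 2)
    x0, x1 = max(0, int(cx - r_out) - 1), min(w, int(cx + r_out) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    # 1 inside, falls to 0 across the soft rim
    a = np.clip((r_out - d) / max(r_out - radius, 1e-6), 0.0, 1.0) * alpha
    patch = canvas[y0:y1, x0:x1]
    patch += a[..., None] * (np.asarray(color, dtype=np.float64) - patch)


def _gaussian_blob(canvas: np.ndarray, cy: float, cx: float, sigma: float,
                   color, alpha: float) -> None:
    """Blend a Gaussian-profile blob onto the canvas, in place."""
    h, w = canvas.shape[:2]
    ext = int(3.0 * sigma) + 1
    y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    a = alpha * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
    patch = canvas[y0:y1, x0:x1]
    patch += a[..., None] * (np.asarray(color, dtype=np.float64) - patch)


def _vessel_mask(rng: np.random.Generator, h: int, w: int, origin: tuple[float, float],
                 field_radius: float, width: int) -> np.ndarray:
    """Random-walk vessel tree as a float alpha mask in [0, 1]."""
    pad = max(int(width), 1) + 2
    mask = np.zeros((h + 2 * pad, w + 2 * pad), dtype=np.float32)
    oy, ox = origin
    n_main = rng.integers(6, 10)
    step = 7.0
    # offsets of a filled disk of the requested half-width, stamped per step
    r = max(int(width), 1)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    stamp = (dy ** 2 + dx ** 2) <= r ** 2
    sdy, sdx = dy[stamp] + pad, dx[stamp] + pad

    def _walk(y, x, ang, n_steps):
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.25)
            y += step * math.sin(ang)
            x += step * math.cos(ang)
            iy, ix = int(y), int(x)
            if not (0 <= iy < h and 0 <= ix < w):
                break
            mask[iy + sdy, ix + sdx] = 1.0
        return y, x, ang

    for _ in range(int(n_main)):
        ang = rng.uniform(0, 2 * math.pi)
        n_steps = int(field_radius * rng.uniform(0.7, 1.0) / step)
        y, x, ang = _walk(oy, ox, ang, n_steps)
        # one side branch per main vessel, half length
        bang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        _walk(y, x, bang, max(n_steps // 2, 1))
    core = mask[pad:pad + h, pad:pad + w]
    return ndimage.gaussian_filter(core, sigma=1.2)


def _low_freq_noise(rng: np.random.Generator, h: int, w: int, cells: int = 12,
                    amplitude: float = 10.0) -> np.ndarray:
    """Smooth brightness mottling, upsampled from a coarse noise grid."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells))
    zoom = (h / cells, w / cells)
    return amplitude * ndimage.zoom(coarse, zoom, order=1, mode="nearest")[:h, :w]


def _seed_for(label: str, seed: int) -> np.random.Generator:
    idx = CLASS_LABELS.index(label)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, idx]))


def generate_image(label: str, seed: int, params: GeneratorParams | None = None,
                   with_metadata: bool = False):
    """Render one labeled synthetic fundus image.

    Deterministic given ``(label, seed, params)``. With ``with_metadata=True``
    returns ``(image, meta)`` where ``meta`` records the drawn optic-disc and
    cup geometry (used to audit the glaucoma signature).
    """
    if label not in CLASS_LABELS:
        raise ParameterError(f"unknown class label {label!r}; expected one of {CLASS_LABELS}")
    params = params or GeneratorParams()
    rng = _seed_for(label, seed)
    full_h, full_w = params.raw_height, params.raw_width
    # render on a half-resolution canvas and upscale at the end: the drawn
    # structures are all larger than 2 px, so this only trades unobservable
    # detail for a ~4x speedup
    rs = 2 if min(full_h, full_w) >= 256 else 1
    h, w = -(-full_h // rs), -(-full_w // rs)
    cy, cx = h / 2.0, w / 2.0
    field_r = 0.47 * min(h, w)

    canvas = np.zeros((h, w, 3), dtype=np.float32)
    # retinal field: warm base with radial falloff and smooth mottling
    yy, xx = np.ogrid[0:h, 0:w]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    inside = np.clip((field_r - d) / (0.04 * field_r), 0.0, 1.0)  # soft field edge
    falloff = 1.0 - 0.35 * np.clip(d / field_r, 0.0, 1.2) ** 2
    base = np.array([185.0, 92.0, 38.0]) * rng.uniform(0.92, 1.08, size=3)
    mottle = _low_freq_noise(rng, h, w)
    for c, scale in enumerate((1.0, 0.8, 0.5)):
        canvas[..., c] = inside * np.clip(base[c] * falloff + scale * mottle, 0, 255)

    # optic disc, offset toward the nasal side
    disc_ang = rng.uniform(-0.35, 0.35)
    disc_dist = rng.uniform(0.45, 0.6) * field_r
    dy_ = cy + disc_dist * math.sin(disc_ang)
    dx_ = cx + disc_dist * math.cos(disc_ang) * rng.choice([-1.0, 1.0])
    disc_r = rng.uniform(0.12, 0.15) * field_r
    if label == "glaucoma":
        # peripapillary atrophy: pale crescent ringing the glaucomatous disc
        _soft_disk(canvas, dy_, dx_, 1.7 * disc_r, (226, 198, 135),
                   alpha=0.55, softness=0.45)
    _soft_disk(canvas, dy_, dx_, disc_r, (232, 195, 120), alpha=0.95)

    # optic cup: small for most classes, enlarged for glaucoma
    if label == "glaucoma":
        area_ratio = params.cup_disc_area_ratio
    else:
        area_ratio = params.normal_cup_area_ratio
    cup_r = math.sqrt(area_ratio) * disc_r
    _soft_disk(canvas, dy_, dx_, cup_r, (252, 238, 190), alpha=0.95)

    # vessel tree rooted at the disc
    width = params.vessel_width_hr if label == "hypertensive_retinopathy" \
        else params.vessel_width_normal
    vmask = _vessel_mask(rng, h, w, (dy_, dx_), field_r, width)
    vcolor = np.array([120.0, 30.0, 22.0])
    canvas += (0.85 * vmask * (inside > 0))[..., None] * (vcolor - canvas)

    if label == "diabetic_retinopathy":
        for _ in range(int(rng.integers(*params.dr_dot_count))):
            ang, rr = rng.uniform(0, 2 * math.pi), rng.uniform(0.1, 0.85) * field_r
            _soft_disk(canvas, cy + rr * math.sin(ang), cx + rr * math.cos(ang),
                       rng.uniform(3, 7), (88, 12, 12), alpha=0.9)
        for _ in range(int(rng.integers(*params.dr_exudate_count))):
            ang, rr = rng.uniform(0, 2 * math.pi), rng.uniform(0.1, 0.8) * field_r
            _gaussian_blob(canvas, cy + rr * math.sin(ang), cx + rr * math.cos(ang),
                           rng.uniform(6, 14), (246, 232, 95), alpha=0.9)
    elif label == "hypertensive_retinopathy":
        for _ in range(int(rng.integers(*params.hr_patch_count))):
            ang, rr = rng.uniform(0, 2 * math.pi), rng.uniform(0.15, 0.8) * field_r
            _gaussian_blob(canvas, cy + rr * math.sin(ang), cx + rr * math.cos(ang),
                           rng.uniform(14, 28), (236, 236, 226), alpha=0.55)

    # sensor noise, shared across channels
    canvas += 2.0 * rng.standard_normal((h, w, 1), dtype=np.float32)

    if label == "contrast":
        canvas = (1.0 - params.haze_strength) * canvas + params.haze_strength * 128.0

    img = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    if rs != 1:
        from PIL import Image
        img = np.asarray(
            Image.fromarray(img).resize((full_w, full_h), Image.BILINEAR))
    if with_metadata:
        meta = {
            "label": label,
            "disc_center": (dy_ * rs, dx_ * rs),
            "disc_radius": disc_r * rs,
            "cup_radius": cup_r * rs,
            "disc_area": math.pi * (disc_r * rs) ** 2,
            "cup_area": math.pi * (cup_r * rs) ** 2,
            "cup_disc_area_ratio": (cup_r / disc_r) ** 2,
        }
        return img, meta
    return img


def generate_dataset(params: GeneratorParams, out_dir) -> DatasetManifest:
    """Write a class-per-subdirectory image folder plus a CSV manifest.

    The train/test split is stratified per class (``round(test_fraction * n)``
    test images per class), seeded, and recorded in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for li, label in enumerate(CLASS_LABELS):
        n = params.n_per_class
        cls_dir = out_dir / label
        cls_dir.mkdir(exist_ok=True)
        split_rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, 1000 + li]))
        n_test = int(round(params.test_fraction * n))
        order = split_rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
        for i in range(n):
            img = generate_image(label, seed=int(params.seed) + 10_000 * li + i, params=params)
            path = cls_dir / f"{label}_{i:04d}.png"
            save_image(img, path)
            rows.append({
                "path": str(path),
                "label": label,
                "split": "test" if i in test_idx else "train",
                "source": "synthetic",
            })
    manifest = DatasetManifest(records=pd.DataFrame(rows))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_image_folder(root, test_fraction: float = 0.15, seed: int = 0) -> DatasetManifest:
    """Build a manifest from any class-per-subdirectory layout of PNG/JPEG files."""
    root = Path(root)
    rows = []
    labels = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not labels:
        raise DataError(f"no class subdirectories under {root}")
    rng = np.random.default_rng(seed)
    for label in labels:
        files = sorted(p for p in (root / label).iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        n_test = int(round(test_fraction * len(files)))
        order = rng.permutation(len(files))
        test_idx = set(order[:n_test].tolist())
        for i, p in enumerate(files):
            rows.append({"path": str(p), "label": label,
                         "split": "test" if i in test_idx else "train",
                         "source": "user"})
    return DatasetManifest(records=pd.DataFrame(rows))


# ----------------------------------------------------------------------------
# published dataset-composition table
# ----------------------------------------------------------------------------

_TABLE3_ROWS = [
    # (source, normal, DR, HR, glaucoma, contrast, printed total)
    ("Eyepacs, Aptos, Messidor", 23125, 23125, 0, 0, 0, 46250),
    ("Eye disease dataset", 0, 0, 0, 50, 100, 150),
    ("Eye disease classification", 250, 250, 0, 250, 250, 1000),
    ("Dataset for different eye diseases", 1637, 0, 0, 1637, 1637, 4101),
    ("DiaRetDB1", 100, 100, 0, 0, 0, 200),
    ("PAK-HR", 3000, 0, 3000, 0, 0, 6000),
    ("DR-Insight", 1000, 0, 4000, 0, 0, 5000),
    ("Imam-HR", 1130, 0, 2040, 0, 0, 3170),
]
_TABLE3_PRINTED_COLUMN_TOTALS = {
    "normal": 30242,
    "diabetic_retinopathy": 23475,
    "hypertensive_retinopathy": 9040,
    "glaucoma": 1937,
    "contrast": 1987,
    "Total": 65871,
}


def table3_manifest() -> DatasetManifest:
    """Packaged multi-source dataset composition table (no images generated).

    Reproduces the published per-source counts verbatim. The printed table is
    internally inconsistent — one source row's cells sum to 4911 against a
    printed row total of 4101, and consequently the printed grand total
    (65,871, the sum of row totals) disagrees with the sum of the column
    totals (66,681). The manifest flags this rather than repairing it.
    """
    cols = ["source"] + list(CLASS_LABELS) + ["Total"]
    df = pd.DataFrame(_TABLE3_ROWS, columns=cols).set_index("source")
    notes = []
    for source, row in df.iterrows():
        cell_sum = int(row[list(CLASS_LABELS)].sum())
        if cell_sum != int(row["Total"]):
            notes.append(
                f"source {source!r}: cells sum to {cell_sum} but printed total is "
                f"{int(row['Total'])}")
    col_sum_total = int(df[list(CLASS_LABELS)].to_numpy().sum())
    row_sum_total = int(df["Total"].sum())
    if col_sum_total != row_sum_total:
        notes.append(
            f"grand total from row totals is {row_sum_total} but the class-column "
            f"cells sum to {col_sum_total}")
    return DatasetManifest(
        records=pd.DataFrame(columns=["path", "label", "split", "source"]),
        source_table=df,
        inconsistent=bool(notes),
        inconsistency_notes=notes,
    )


def table3_printed_column_totals() -> dict:
    """Column totals as printed at the foot of the published table."""
    return dict(_TABLE3_PRINTED_COLUMN_TOTALS)
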