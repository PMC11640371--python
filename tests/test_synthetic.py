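"""Synthetic fundus generator: determinism, class signatures, manifests."""

import numpy as np
import pytest

from cadeye import DataError, ParameterError
from cadeye.image import load_image
from cadeye.synthetic import (CLASS_LABELS, GeneratorParams, generate_dataset,
                              generate_image, load_image_folder,
                              table3_manifest, table3_printed_column_totals)

SMALL = GeneratorParams(raw_height=128, raw_width=112, n_per_class=4, seed=0)


def test_determinism_and_raw_size():
    a = generate_image("normal", 1, SMALL)
    b = generate_image("normal", 1, SMALL)
    assert np.array_equal(a, b)
    assert a.shape == (128, 112, 3) and a.dtype == np.uint8


def test_unknown_label_rejected():
    with pytest.raises(ParameterError):
        generate_image("cataract_xyz", 0, SMALL)


def test_glaucoma_cup_geometry_self_report_vs_pixel_oracle():
    """The generator's reported cup/disc area ratio must exceed 0.6 and match
    the area of the actually drawn bright cup."""
    img, meta = generate_image("glaucoma", 7, with_metadata=True)
    assert meta["cup_disc_area_ratio"] > 0.6
    # pixel oracle: the cup is the only structure with blue channel >= 150;
    # vessels rooted at the disc occlude part of it, so the measured area is
    # a large fraction of pi * r^2, never more than it
    cup_pixels = int((img[..., 2] >= 150).sum())
    assert 0.5 * meta["cup_area"] < cup_pixels < 1.1 * meta["cup_area"]
    # and the glaucomatous cup dwarfs the physiological cup of a normal eye
    normal_img, normal_meta = generate_image("normal", 7, with_metadata=True)
    assert normal_meta["cup_disc_area_ratio"] < 0.3
    assert cup_pixels > 3 * int((normal_img[..., 2] >= 150).sum())


def test_contrast_class_reduces_intensity_spread():
    normal = generate_image("normal", 3, SMALL)
    hazy = generate_image("contrast", 3, SMALL)
    assert hazy.std() < normal.std()


def test_generate_dataset_layout_and_split(tmp_path):
    params = GeneratorParams(raw_height=96, raw_width=96, n_per_class=10,
                             seed=5, test_fraction=0.2)
    manifest = generate_dataset(params, tmp_path / "ds")
    assert len(manifest.records) == 50
    for label in CLASS_LABELS:
        files = list((tmp_path / "ds" / label).glob("*.png"))
        assert len(files) == 10
        sub = manifest.records[manifest.records["label"] == label]
        assert (sub["split"] == "test").sum() == 2  # round(0.2 * 10)
    # manifest counts equal on-disk counts
    assert (tmp_path / "ds" / "manifest.csv").exists()
    for p in manifest.records["path"]:
        img = load_image(p)
        assert img.shape == (96, 96, 3)


def test_generate_dataset_reproducible_bytes(tmp_path):
    params = GeneratorParams(raw_height=96, raw_width=96, n_per_class=2, seed=9)
    m1 = generate_dataset(params, tmp_path / "a")
    m2 = generate_dataset(params, tmp_path / "b")
    assert m1.records["label"].tolist() == m2.records["label"].tolist()
    assert m1.records["split"].tolist() == m2.records["split"].tolist()
    for p1, p2 in zip(m1.records["path"], m2.records["path"]):
        with open(p1, "rb") as f1, open(p2, "rb") as f2:
            assert f1.read() == f2.read()


def test_stratified_split_fraction(tmp_path):
    params = GeneratorParams(raw_height=96, raw_width=96, n_per_class=100,
                             seed=2, test_fraction=0.15)
    manifest = generate_dataset(params, tmp_path / "ds")
    for label in CLASS_LABELS:
        sub = manifest.records[manifest.records["label"] == label]
        assert (sub["split"] == "test").sum() == 15


def test_nearest_centroid_baseline_beats_chance(tmp_path):
    """Classes must be separable by construction: a trivial nearest-centroid
    classifier on per-channel mean intensities beats the 20% chance level."""
    params = GeneratorParams(raw_height=128, raw_width=112, n_per_class=100, seed=11)
    feats, labels = [], []
    for li, label in enumerate(CLASS_LABELS):
        for i in range(params.n_per_class):
            img = generate_image(label, 500 + 1000 * li + i, params)
            feats.append(img.reshape(-1, 3).mean(axis=0))
            labels.append(li)
    x = np.asarray(feats)
    y = np.asarray(labels)
    centroids = np.stack([x[y == k].mean(axis=0) for k in range(5)])
    pred = ((x[:, None, :] - centroids[None]) ** 2).sum(-1).argmin(1)
    assert (pred == y).mean() > 0.2


def test_load_image_folder_roundtrip(tiny_dataset):
    manifest, params, root = tiny_dataset
    loaded = load_image_folder(root, test_fraction=0.2, seed=0)
    assert sorted(loaded.records["label"].unique()) == sorted(CLASS_LABELS)
    assert len(loaded.records) == len(manifest.records)


class TestTable3Manifest:
    def test_row_totals_sum_to_published_grand_total(self):
        m = table3_manifest()
        assert int(m.source_table["Total"].sum()) == 65871

    def test_published_column_sums(self):
        m = table3_manifest()
        cols = m.source_table
        assert int(cols["normal"].sum()) == 30242
        assert int(cols["hypertensive_retinopathy"].sum()) == 9040
        assert int(cols["diabetic_retinopathy"].sum()) == 23475
        assert int(cols["glaucoma"].sum()) == 1937

    def test_internal_inconsistency_flagged_not_repaired(self):
        m = table3_manifest()
        assert m.inconsistent
        assert any("4911" in note for note in m.inconsistency_notes)
        # the printed cells are preserved verbatim
        row = m.source_table.loc["Dataset for different eye diseases"]
        assert int(row["Total"]) == 4101
        assert int(row["normal"]) == int(row["glaucoma"]) == int(row["contrast"]) == 1637
        totals = table3_printed_column_totals()
        assert totals["Total"] == 65871
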