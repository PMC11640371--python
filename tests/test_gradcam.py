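"""Grad-CAM heatmaps and overlay rendering."""

import numpy as np
import pytest

from cadeye import ParameterError
from cadeye.backbones import build_backbone, extract, gap
from cadeye.fluorescence import hot_lut
from cadeye.fusion import build_fusion_model
from cadeye.gradcam import Heatmap, gradcam, overlay
from cadeye.image import to_float


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    bb_a = build_backbone("mobilenet_v2_like", "tiny", 0)
    bb_b = build_backbone("efficientnet_b0_like", "tiny", 0)
    return img, bb_a, bb_b


def _channel_mean_model(bb_a, bb_b, img, target=0):
    """Head whose target-class logit equals the pooled value of one chosen
    backbone-a channel (a channel with positive pooled activation, so the
    ReLU in the hidden layer is transparent)."""
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=0)
    pooled = gap(extract(bb_a, to_float(img)[None]))[0]
    k = int(np.argmax(pooled))          # a strictly positive channel
    assert pooled[k] > 0
    model.layers[0].w[...] = 0.0
    model.layers[0].b[...] = 0.0
    model.layers[0].w[k, 0] = 1.0       # hidden unit 0 = relu(pooled_k)
    model.output.w[...] = 0.0
    model.output.b[...] = 0.0
    model.output.w[0, target] = 1.0     # logit_target = hidden unit 0
    return model, k


def test_heatmap_proportional_to_chosen_channel(setup):
    """Analytic oracle: when the class score is the mean of channel k, the
    map must be the (rectified, normalized) activation of channel k."""
    img, bb_a, bb_b = setup
    model, k = _channel_mean_model(bb_a, bb_b, img)
    hm = gradcam(model, (bb_a, bb_b), img, target=0, which="a")
    fmap = extract(bb_a, to_float(img)[None])[0, :, :, k]
    expected = np.maximum(fmap, 0.0)
    # compare after identical upsampling/normalization
    from cadeye.gradcam import _normalize_upsample
    expected = _normalize_upsample(expected, img.shape[:2])
    assert np.allclose(hm.values, expected, atol=1e-6)


def test_zero_gradient_gives_zero_heatmap(setup):
    img, bb_a, bb_b = setup
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=0)
    model.output.w[...] = 0.0   # no path from features to any logit
    hm = gradcam(model, (bb_a, bb_b), img, target=2)
    assert not np.isnan(hm.values).any()
    assert hm.values.max() == 0.0


def test_heatmap_range_and_shape(setup):
    img, bb_a, bb_b = setup
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=1)
    for which in ("a", "b", "combined"):
        hm = gradcam(model, (bb_a, bb_b), img, target=1, which=which)
        assert hm.values.shape == img.shape[:2]
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0


def test_upsampling_preserves_argmax_location(setup):
    img, bb_a, bb_b = setup
    model, k = _channel_mean_model(bb_a, bb_b, img)
    fmap = extract(bb_a, to_float(img)[None])[0, :, :, k]
    cam = np.maximum(fmap, 0.0)
    ci, cj = np.unravel_index(cam.argmax(), cam.shape)
    hm = gradcam(model, (bb_a, bb_b), img, target=0, which="a")
    ui, uj = np.unravel_index(hm.values.argmax(), hm.values.shape)
    cell_h = img.shape[0] / cam.shape[0]
    cell_w = img.shape[1] / cam.shape[1]
    assert abs(ui - ci * cell_h) <= 2 * cell_h
    assert abs(uj - cj * cell_w) <= 2 * cell_w


def test_bad_target_rejected(setup):
    img, bb_a, bb_b = setup
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               5, "basic", seed=0)
    with pytest.raises(ParameterError):
        gradcam(model, (bb_a, bb_b), img, target=9)
    with pytest.raises(ParameterError):
        gradcam(model, (bb_a, bb_b), img, target="glaucoma")  # no class names


class TestOverlay:
    def _heatmap(self, rng, shape):
        v = rng.random(shape)
        return Heatmap(values=v / v.max(), target_class=0)

    def test_opacity_extremes(self, rng, random_image):
        hm = self._heatmap(rng, random_image.shape[:2])
        assert np.array_equal(overlay(random_image, hm, 0.0), random_image)
        pure = overlay(random_image, hm, 1.0)
        lut = hot_lut()
        idx = np.clip(np.floor(hm.values * 255.0 + 0.5), 0, 255).astype(np.uint8)
        assert np.array_equal(pure, lut[idx])

    def test_half_blend_is_pixel_average(self, rng, random_image):
        hm = self._heatmap(rng, random_image.shape[:2])
        lut = hot_lut()
        idx = np.clip(np.floor(hm.values * 255.0 + 0.5), 0, 255).astype(np.uint8)
        colored = lut[idx].astype(np.float64)
        expected = np.clip(np.floor(
            (random_image.astype(np.float64) + colored) / 2.0 + 0.5), 0, 255)
        assert np.array_equal(overlay(random_image, hm, 0.5), expected.astype(np.uint8))

    def test_opacity_out_of_range(self, rng, random_image):
        hm = self._heatmap(rng, random_image.shape[:2])
        with pytest.raises(ParameterError):
            overlay(random_image, hm, 1.5)
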