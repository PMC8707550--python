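import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from augforge import RandomSource, RasterImage, make_fixtures
from augforge.photometric_aug import (
    ColorShift,
    ContrastBounds,
    app6,
    app7,
    app8,
    color_shift,
    contrast_stretch,
    draw_jitter_offset,
    gaussian_blur,
    histogram_specification,
    jitter_hsv,
    lalphabeta_to_rgb,
    reinhard_transfer,
    rgb_to_lalphabeta,
    sharpen_subtract,
)


def _gray(value=0.5, shape=(8, 8)):
    return RasterImage(np.full((*shape, 3), value))


class TestContrastStretch:
    def test_full_range_bounds_are_identity(self, rgb_set):
        img = rgb_set[0][0]
        out = contrast_stretch(img, ContrastBounds(0, 255))
        assert np.allclose(out.pixels, img.pixels, atol=1e-12)

    def test_mapping_rule(self):
        img = RasterImage(np.array([[[50 / 255], [150 / 255], [250 / 255]]]).reshape(1, 3, 1))
        out = contrast_stretch(img, ContrastBounds(100, 200))
        assert out.pixels[0, 0, 0] == 0.0           # below a -> 0
        assert out.pixels[0, 2, 0] == 1.0           # above b -> 255
        assert np.isclose(out.pixels[0, 1, 0], 127.5 / 255)  # linear map

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ContrastBounds(200, 100)
        with pytest.raises(ValueError):
            ContrastBounds(-1, 100)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.integers(0, 100),
        b=st.integers(150, 255),
        seed=st.integers(0, 100),
    )
    def test_monotone_nondecreasing(self, a, b, seed):
        vals = np.sort(RandomSource(seed).random(64))
        img = RasterImage(vals.reshape(8, 8, 1))
        out = contrast_stretch(img, ContrastBounds(a, b)).pixels.ravel()
        assert np.all(np.diff(out) >= -1e-12)


class TestSharpen:
    def test_constant_image_unchanged(self):
        out = sharpen_subtract(_gray(0.4))
        assert np.allclose(out.pixels, 0.4, atol=1e-10)

    def test_step_edge_overshoot(self):
        # 1-D oracle: unsharp masking overshoots on both sides of a step
        sig = np.array([0.3] * 4 + [0.7] * 4).reshape(1, 8, 1)
        out = sharpen_subtract(RasterImage(sig)).pixels.ravel()
        assert out[3] < 0.3 and out[4] > 0.7

    def test_literal_variant_is_bare_difference(self):
        img = _gray(0.4)
        out = sharpen_subtract(img, literal=True)
        assert np.allclose(out.pixels, 0.0, atol=1e-10)

    def test_shape_preserved(self, rgb_set):
        img = rgb_set[0][0]
        assert sharpen_subtract(img).shape == img.shape


class TestColorShift:
    def test_zero_shift_identity(self, rgb_set):
        img = rgb_set[0][0]
        assert np.array_equal(color_shift(img, ColorShift(0, 0, 0)).pixels, img.pixels)

    def test_additive_arithmetic(self):
        out = color_shift(_gray(0.5), ColorShift(51, 0, 0))
        assert np.allclose(out.pixels[:, :, 0], 0.5 + 51 / 255)
        assert np.allclose(out.pixels[:, :, 1:], 0.5)

    def test_saturating_clip(self):
        out = color_shift(_gray(250 / 255), ColorShift(20, 20, 20))
        assert np.all(out.pixels == 1.0)

    def test_grayscale_rejected(self, gray_set):
        with pytest.raises(ValueError, match="3-channel"):
            color_shift(gray_set[0][0], ColorShift(1, 2, 3))


class TestJitterHSV:
    def test_zero_offset_is_identity(self, rgb_set):
        img = rgb_set[0][0]
        for attr in ("hue", "saturation", "brightness"):
            out = jitter_hsv(img, attr, offset=0.0)
            assert np.abs(out.pixels - img.pixels).max() <= 1e-6
        out = jitter_hsv(img, "contrast", offset=1.0)
        assert np.abs(out.pixels - img.pixels).max() <= 1e-6

    def test_gray_image_invariant_under_hue_jitter(self):
        out = jitter_hsv(_gray(0.5), "hue", offset=0.1)
        assert np.abs(out.pixels - 0.5).max() <= 1e-6

    @pytest.mark.parametrize(
        "attr,lo,hi",
        [
            ("hue", 0.05, 0.15),
            ("saturation", -0.4, -0.1),
            ("brightness", -0.3, -0.1),
            ("contrast", 1.2, 1.4),
        ],
    )
    def test_drawn_offsets_stay_in_range(self, attr, lo, hi):
        rng = RandomSource(0)
        draws = np.array([draw_jitter_offset(attr, rng) for _ in range(10_000)])
        assert draws.min() >= lo and draws.max() <= hi

    def test_grayscale_rejected(self, gray_set):
        with pytest.raises(ValueError, match="3-channel"):
            jitter_hsv(gray_set[0][0], "hue", offset=0.1)


class TestApp6App7:
    def test_app6_three_outputs_and_determinism(self, rgb_set):
        img = rgb_set[0][0]
        a = app6(img, RandomSource(4))
        b = app6(img, RandomSource(4))
        assert len(a) == 3
        assert all(o.shape == img.shape for o in a)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_app7_seven_outputs(self, rgb_set):
        img = rgb_set[0][0]
        outs = app7(img, RandomSource(4))
        assert len(outs) == 7
        assert all(o.shape == img.shape for o in outs)

    def test_blur_output_within_input_range(self, rgb_set):
        img = rgb_set[0][0]
        out = gaussian_blur(img, 3.0)
        assert out.pixels.min() >= img.pixels.min() - 1e-10
        assert out.pixels.max() <= img.pixels.max() + 1e-10


class TestHistogramSpecification:
    def test_self_target_is_identity_up_to_quantization(self, rgb_set):
        img = rgb_set[0][0]
        out = histogram_specification(img, img)
        assert np.abs(out.pixels - img.pixels).max() <= 1 / 255

    def test_constant_target_maps_everything_to_it(self):
        src = RasterImage(RandomSource(1).random((4, 4, 3)))
        out = histogram_specification(src, _gray(0.25, (4, 4)))
        assert np.abs(out.pixels - 0.25).max() <= 1e-9

    def test_rank_order_preserved_per_channel(self):
        src = RasterImage(RandomSource(2).random((8, 8, 3)))
        tgt = RasterImage(RandomSource(3).random((8, 8, 3)))
        out = histogram_specification(src, tgt)
        for c in range(3):
            s = src.pixels[:, :, c].ravel()
            o = out.pixels[:, :, c].ravel()
            order = np.argsort(s, kind="stable")
            assert np.all(np.diff(o[order]) >= -1e-12)

    def test_pixel_position_invariance(self):
        # the map depends only on values, not locations
        src = RandomSource(4).random((6, 6, 3))
        tgt = RasterImage(RandomSource(5).random((6, 6, 3)))
        perm = RandomSource(6).generator.permutation(36)
        shuffled = src.reshape(36, 3)[perm].reshape(6, 6, 3)
        out1 = histogram_specification(RasterImage(src), tgt).pixels.reshape(36, 3)[perm]
        out2 = histogram_specification(RasterImage(shuffled), tgt).pixels.reshape(36, 3)
        assert np.allclose(out1, out2, atol=1e-12)

    def test_channel_mismatch_rejected(self, gray_set, rgb_set):
        with pytest.raises(ValueError):
            histogram_specification(rgb_set[0][0], gray_set[0][0])


class TestReinhard:
    def test_one_pixel_conversion_against_hand_computation(self):
        # (0.2, 0.4, 0.6) through the published RGB->LMS->log->lalphabeta chain
        lab = rgb_to_lalphabeta(np.array([[[0.2, 0.4, 0.6]]]))
        assert np.allclose(lab[0, 0], [-0.666033, -0.165374, -0.038550], atol=1e-4)
        back = lalphabeta_to_rgb(lab)
        assert np.allclose(back[0, 0], [0.2, 0.4, 0.6], atol=1e-6)

    def test_self_target_is_identity(self, rgb_set):
        img = rgb_set[0][0]
        out = reinhard_transfer(img, img)
        assert np.abs(out.pixels - img.pixels).max() <= 1e-4

    def test_moments_match_target_in_lalphabeta(self, rgb_set):
        src, tgt = rgb_set[0][0], rgb_set[7][0]
        out = reinhard_transfer(src, tgt, clip=False)
        lab_out = rgb_to_lalphabeta(out.pixels)
        lab_tgt = rgb_to_lalphabeta(tgt.pixels)
        for c in range(3):
            assert abs(lab_out[:, :, c].mean() - lab_tgt[:, :, c].mean()) <= 1e-4
            assert abs(lab_out[:, :, c].std() - lab_tgt[:, :, c].std()) <= 1e-4

    def test_zero_spread_channel_is_mean_shifted(self):
        src = _gray(0.5)
        tgt = RasterImage(RandomSource(7).random((8, 8, 3)))
        out = reinhard_transfer(src, tgt, clip=False)
        lab_tgt = rgb_to_lalphabeta(tgt.pixels)
        lab_out = rgb_to_lalphabeta(out.pixels)
        for c in range(3):
            assert np.allclose(lab_out[:, :, c], lab_tgt[:, :, c].mean(), atol=1e-9)

    def test_grayscale_rejected(self, gray_set, rgb_set):
        with pytest.raises(ValueError):
            reinhard_transfer(gray_set[0][0], rgb_set[0][0])


class TestApp8:
    def test_two_outputs_and_determinism(self, rgb_set):
        img, label = rgb_set[0]
        a = app8(img, label, rgb_set, RandomSource(9))
        b = app8(img, label, rgb_set, RandomSource(9))
        assert len(a) == 2
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_target_is_never_the_image_itself(self):
        # a 2-member class forces the single other image to be the target
        ds = make_fixtures(2, 2, (8, 8), channels=3, seed=0)
        img, label = ds[0]
        peer = ds[1][0]
        out = app8(img, label, ds, RandomSource(0))
        expected = histogram_specification(img, peer)
        assert np.array_equal(out[0].pixels, expected.pixels)

    def test_no_peer_raises(self):
        from augforge import PeerShortageError

        ds = make_fixtures(2, 1, (8, 8), channels=3, seed=0)
        img, label = ds[0]
        with pytest.raises(PeerShortageError):
            app8(img, label, ds, RandomSource(0))
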