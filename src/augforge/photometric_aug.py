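"""Photometric augmenters.

App6: linear contrast stretch between sampled bounds, unsharp-mask sharpening,
and per-channel integer color shifts. App7: HSV jitter of hue / saturation /
brightness / contrast, random-sigma Gaussian blur, fixed-parameter sharpening
and a color shift — seven outputs. App8: histogram specification and Reinhard
color transfer toward a randomly drawn same-class target.

All operators preserve shape; color operators require 3-channel input and
raise on grayscale rather than silently promoting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.exposure import match_histograms

from .core_io import (
    Config,
    LabeledImageSet,
    RandomSource,
    RasterImage,
    ensure_config,
    sample_peers,
)

__all__ = [
    "ContrastBounds",
    "ColorShift",
    "contrast_stretch",
    "sharpen_subtract",
    "color_shift",
    "jitter_hsv",
    "gaussian_blur",
    "unsharp_mask",
    "histogram_specification",
    "reinhard_transfer",
    "rgb_to_lalphabeta",
    "lalphabeta_to_rgb",
    "app6",
    "app7",
    "app8",
]


@dataclass(frozen=True)
class ContrastBounds:
    """Lower/upper intensities (8-bit scale) mapped to 0 and 255."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b <= 255):
            raise ValueError(f"need 0 <= a < b <= 255, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class ColorShift:
    """Additive per-channel shifts on the 8-bit scale."""

    shift_r: int
    shift_g: int
    shift_b: int


def _require_color(image: RasterImage, op: str) -> None:
    if image.channels != 3:
        raise ValueError(f"{op} requires a 3-channel image (got {image.channels} channel)")


def contrast_stretch(image: RasterImage, bounds: ContrastBounds) -> RasterImage:
    """Linearly map intensities in [a, b] to the full range; saturate outside.

    Monotone non-decreasing in input intensity.
    """
    a = bounds.a / 255.0
    b = bounds.b / 255.0
    out = (image.pixels - a) / (b - a)
    return RasterImage(np.clip(out, 0.0, 1.0), image.colorspace)


def _blur(px: np.ndarray, sigma: float) -> np.ndarray:
    out = np.empty_like(px)
    for c in range(px.shape[2]):
        out[:, :, c] = ndimage.gaussian_filter(px[:, :, c], sigma, mode="nearest")
    return out


def sharpen_subtract(
    image: RasterImage, sigma: float = 1.0, literal: bool = False
) -> RasterImage:
    """Sharpen by Gaussian blur (variance sigma**2) and high-pass feedback.

    Default: unsharp masking, out = img + (img - blur), which boosts edges
    while keeping flat regions intact. ``literal=True`` returns the bare
    difference img - blur instead (an edge image).
    """
    blur = _blur(image.pixels, sigma)
    out = image.pixels - blur if literal else image.pixels + (image.pixels - blur)
    return RasterImage(np.clip(out, 0.0, 1.0), image.colorspace)


def color_shift(image: RasterImage, shifts: ColorShift) -> RasterImage:
    """Add one constant (8-bit scale) to each RGB channel, then clip."""
    _require_color(image, "color_shift")
    delta = np.array([shifts.shift_r, shifts.shift_g, shifts.shift_b]) / 255.0
    return RasterImage(np.clip(image.pixels + delta[None, None, :], 0.0, 1.0), image.colorspace)


def gaussian_blur(image: RasterImage, sigma: float) -> RasterImage:
    return RasterImage(np.clip(_blur(image.pixels, sigma), 0.0, 1.0), image.colorspace)


def unsharp_mask(image: RasterImage, radius: float, strength: float) -> RasterImage:
    """out = img + strength * (img - gaussian_blur(img, radius))."""
    blur = _blur(image.pixels, radius)
    out = image.pixels + strength * (image.pixels - blur)
    return RasterImage(np.clip(out, 0.0, 1.0), image.colorspace)


_JITTER_ATTRS = ("hue", "saturation", "brightness", "contrast")


def draw_jitter_offset(attribute: str, rng: RandomSource, config: Config | None = None) -> float:
    """Uniform draw from the configured range of one HSV jitter attribute."""
    if attribute not in _JITTER_ATTRS:
        raise ValueError(f"attribute must be one of {_JITTER_ATTRS}")
    lo, hi = ensure_config(config).get(f"photo.jitter.{attribute}")
    return float(rng.uniform(lo, hi))


def jitter_hsv(
    image: RasterImage,
    attribute: str,
    rng: RandomSource | None = None,
    offset: float | None = None,
    config: Config | None = None,
) -> RasterImage:
    """Jitter one HSV attribute by a random draw from its configured range.

    Hue offsets wrap modulo 1; saturation and brightness offsets are added and
    clipped; contrast scales the value channel about mid-gray. Pass ``offset``
    to bypass the draw (test hook).
    """
    if attribute not in _JITTER_ATTRS:
        raise ValueError(f"attribute must be one of {_JITTER_ATTRS}")
    _require_color(image, "jitter_hsv")
    cfg = ensure_config(config)
    if offset is None:
        if rng is None:
            raise ValueError("need rng when offset is not given")
        offset = draw_jitter_offset(attribute, rng, cfg)
    hsv = skcolor.rgb2hsv(np.clip(image.pixels, 0.0, 1.0))
    if attribute == "hue":
        hsv[:, :, 0] = (hsv[:, :, 0] + offset) % 1.0
    elif attribute == "saturation":
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] + offset, 0.0, 1.0)
    elif attribute == "brightness":
        hsv[:, :, 2] = np.clip(hsv[:, :, 2] + offset, 0.0, 1.0)
    else:  # contrast: multiplicative scaling of the value channel about 0.5
        hsv[:, :, 2] = np.clip((hsv[:, :, 2] - 0.5) * offset + 0.5, 0.0, 1.0)
    return RasterImage(np.clip(skcolor.hsv2rgb(hsv), 0.0, 1.0), image.colorspace)


def _sample_color_shift(rng: RandomSource, cfg: Config) -> ColorShift:
    lo, hi = cfg.get("photo.shift_range")
    r, g, b = (int(rng.integers(lo, hi + 1)) for _ in range(3))
    return ColorShift(r, g, b)


def app6(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Contrast stretch with sampled bounds, sharpening, and a color shift."""
    _require_color(image, "App6")
    cfg = ensure_config(config)
    a_lo, a_hi = cfg.get("photo.contrast_a_range")
    b_lo, b_hi = cfg.get("photo.contrast_b_range")
    bounds = ContrastBounds(
        float(rng.integers(a_lo, a_hi + 1)), float(rng.integers(b_lo, b_hi + 1))
    )
    return [
        contrast_stretch(image, bounds),
        sharpen_subtract(image, 1.0, literal=bool(cfg.get("photo.sharpen_literal"))),
        color_shift(image, _sample_color_shift(rng, cfg)),
    ]


def app7(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Seven outputs: four HSV jitters, random blur, fixed sharpen, color shift."""
    _require_color(image, "App7")
    cfg = ensure_config(config)
    outs = [jitter_hsv(image, attr, rng, config=cfg) for attr in _JITTER_ATTRS]
    s_lo, s_hi = cfg.get("photo.jitter.blur_sigma")
    outs.append(gaussian_blur(image, float(rng.uniform(s_lo, s_hi))))
    outs.append(
        unsharp_mask(
            image,
            cfg.get("photo.jitter.sharpen_radius"),
            cfg.get("photo.jitter.sharpen_strength"),
        )
    )
    outs.append(color_shift(image, _sample_color_shift(rng, cfg)))
    return outs


# ---------------------------------------------------------------------------
# App8: histogram specification and Reinhard transfer
# ---------------------------------------------------------------------------

def histogram_specification(source: RasterImage, target: RasterImage) -> RasterImage:
    """Monotone per-channel CDF matching of the source histogram to the target's."""
    if source.channels != target.channels:
        raise ValueError("source and target must have the same channel count")
    _require_color(source, "histogram_specification")
    out = match_histograms(source.pixels, target.pixels, channel_axis=-1)
    return RasterImage(np.clip(out, 0.0, 1.0), source.colorspace)


# Ruderman log-opponent color space: RGB -> LMS -> log10 -> lalphabeta.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LMS_FLOOR = 1e-8  # log-domain guard for zero pixels


def rgb_to_lalphabeta(px: np.ndarray) -> np.ndarray:
    lms = px @ _RGB2LMS.T
    lms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return lms @ _LMS2LAB.T


def lalphabeta_to_rgb(lab: np.ndarray) -> np.ndarray:
    lms = 10.0 ** (lab @ _LAB2LMS.T)
    return lms @ _LMS2RGB.T


def reinhard_transfer(
    source: RasterImage, target: RasterImage, clip: bool = True
) -> RasterImage:
    """Match the source's per-channel mean and spread to the target's in the
    decorrelated log-opponent (lalphabeta) space — the classic color-transfer /
    stain-normalization recipe.

    A zero-spread source channel is mean-shifted with unit scale. With
    ``clip=False`` the raw back-transformed values are returned (moments in
    lalphabeta then equal the target's exactly).
    """
    _require_color(source, "reinhard_transfer")
    _require_color(target, "reinhard_transfer")
    lab_s = rgb_to_lalphabeta(source.pixels)
    lab_t = rgb_to_lalphabeta(target.pixels)
    out = np.empty_like(lab_s)
    for c in range(3):
        mu_s, sd_s = lab_s[:, :, c].mean(), lab_s[:, :, c].std()
        mu_t, sd_t = lab_t[:, :, c].mean(), lab_t[:, :, c].std()
        scale = (sd_t / sd_s) if sd_s > 1e-12 else 1.0  # flat channel: mean shift only
        out[:, :, c] = (lab_s[:, :, c] - mu_s) * scale + mu_t
    rgb = lalphabeta_to_rgb(out)
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return RasterImage(rgb, source.colorspace)


def app8(
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
) -> list[RasterImage]:
    """Two outputs mapping the image onto one same-class target: histogram
    specification and Reinhard transfer (one shared target draw)."""
    _require_color(image, "App8")
    target = sample_peers(dataset, label, 1, rng, exclude=image)[0]
    return [histogram_specification(image, target), reinhard_transfer(image, target)]
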