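"""Geometric augmenters App1–App3: reflection, anisotropic scaling, rotation,
translation and shear, composed as a single affine warp about the image center.

App1 reflects (fair coin per axis) and upscales each axis by an independent
factor in [1, 2], then center-crops back to the input size. App2 adds rotation
in [-10, 10] degrees, translation in [0, 5] pixels per axis and shear in
[0, 30] degrees per axis. App3 is App2 without shear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Config, RandomSource, RasterImage, ensure_config

__all__ = ["GeometricParams", "sample_params", "apply_geometric", "app1", "app2", "app3"]


@dataclass(frozen=True)
class GeometricParams:
    reflect_lr: bool = False
    reflect_tb: bool = False
    scale_x: float = 1.0
    scale_y: float = 1.0
    rotation_deg: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    shear_x_deg: float = 0.0
    shear_y_deg: float = 0.0

    def is_identity(self) -> bool:
        return (
            not self.reflect_lr
            and not self.reflect_tb
            and self.scale_x == 1.0
            and self.scale_y == 1.0
            and self.rotation_deg == 0.0
            and self.shift_x == 0.0
            and self.shift_y == 0.0
            and self.shear_x_deg == 0.0
            and self.shear_y_deg == 0.0
        )


_MODES = ("App1", "App2", "App3")


def sample_params(mode: str, rng: RandomSource, config: Config | None = None) -> GeometricParams:
    """Draw one parameter set for the given mode.

    Every random field is uniform on its configured interval; reflections are
    independent coin flips. Fields outside the mode's scope stay at identity:
    App1 has no rotation/shift/shear, App3 no shear.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    cfg = ensure_config(config)
    s_lo, s_hi = cfg.get("geo.scale_range")
    p_ref = cfg.get("geo.reflect_prob")
    reflect_lr = bool(rng.random() < p_ref)
    reflect_tb = bool(rng.random() < p_ref)
    scale_x = float(rng.uniform(s_lo, s_hi))
    scale_y = float(rng.uniform(s_lo, s_hi))
    rotation = shift_x = shift_y = shear_x = shear_y = 0.0
    if mode in ("App2", "App3"):
        r_lo, r_hi = cfg.get("geo.rot_range")
        t_lo, t_hi = cfg.get("geo.shift_range")
        rotation = float(rng.uniform(r_lo, r_hi))
        shift_x = float(rng.uniform(t_lo, t_hi))
        shift_y = float(rng.uniform(t_lo, t_hi))
        if cfg.get("geo.random_shift_sign"):
            shift_x *= 1.0 if rng.random() < 0.5 else -1.0
            shift_y *= 1.0 if rng.random() < 0.5 else -1.0
    if mode == "App2":
        h_lo, h_hi = cfg.get("geo.shear_range")
        shear_x = float(rng.uniform(h_lo, h_hi))
        shear_y = float(rng.uniform(h_lo, h_hi))
    return GeometricParams(
        reflect_lr=reflect_lr,
        reflect_tb=reflect_tb,
        scale_x=scale_x,
        scale_y=scale_y,
        rotation_deg=rotation,
        shift_x=shift_x,
        shift_y=shift_y,
        shear_x_deg=shear_x,
        shear_y_deg=shear_y,
    )


def _forward_matrix(p: GeometricParams) -> np.ndarray:
    """Homogeneous forward map in centered (x, y) coordinates.

    Composition order: reflect -> scale -> rotate -> shear -> translate.
    """
    def mat(a, b, c, d, tx=0.0, ty=0.0):
        return np.array([[a, b, tx], [c, d, ty], [0.0, 0.0, 1.0]])

    F = mat(-1.0 if p.reflect_lr else 1.0, 0.0, 0.0, -1.0 if p.reflect_tb else 1.0)
    S = mat(p.scale_x, 0.0, 0.0, p.scale_y)
    th = np.deg2rad(p.rotation_deg)
    R = mat(np.cos(th), -np.sin(th), np.sin(th), np.cos(th))
    Sh = mat(1.0, np.tan(np.deg2rad(p.shear_x_deg)), np.tan(np.deg2rad(p.shear_y_deg)), 1.0)
    T = mat(1.0, 0.0, 0.0, 1.0, p.shift_x, p.shift_y)
    return T @ Sh @ R @ S @ F


def apply_geometric(image: RasterImage, p: GeometricParams) -> RasterImage:
    """Warp the image by the affine map defined by ``p``.

    The transform acts about the image center; the output keeps the input's
    H×W×C (upscaling is an implicit center crop). Out-of-frame samples
    replicate the nearest edge pixel; bilinear interpolation elsewhere.
    All-identity params are an exact no-op.
    """
    if p.is_identity():
        return RasterImage(image.pixels.copy(), image.colorspace)
    M = _forward_matrix(p)
    Minv = np.linalg.inv(M)
    # scipy maps output index (row, col) -> input index; our matrix is in
    # (x, y) = (col, row) centered coordinates, so swap and offset.
    A_xy = Minv[:2, :2]
    t_xy = Minv[:2, 2]
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    A_rc = swap @ A_xy @ swap
    center = np.array([(image.height - 1) / 2.0, (image.width - 1) / 2.0])
    offset = center + swap @ t_xy - A_rc @ center
    out = np.empty_like(image.pixels)
    for c in range(image.channels):
        out[:, :, c] = ndimage.affine_transform(
            image.pixels[:, :, c], A_rc, offset=offset, order=1, mode="nearest"
        )
    return RasterImage(np.clip(out, 0.0, 1.0), image.colorspace)


def _run(mode: str, count: int, image: RasterImage, rng: RandomSource, config: Config | None):
    return [apply_geometric(image, sample_params(mode, rng, config)) for _ in range(count)]


def app1(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Three reflected-and-rescaled variants of the input."""
    return _run("App1", 3, image, rng, config)


def app2(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Six variants with reflection, scaling, rotation, translation and shear."""
    return _run("App2", 6, image, rng, config)


def app3(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Four variants as App2 but without shear."""
    return _run("App3", 4, image, rng, config)
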