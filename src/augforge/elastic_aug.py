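"""Elastic deformation (App9): warping by random per-pixel displacement fields.

Six outputs per image: three warps with raw i.i.d. Uniform[-1, 1] fields scaled
by alpha in {7000, 1000, 13000}, and three warps whose unit fields are first
low-pass filtered (circular averaging, Gaussian, Laplacian-of-Gaussian) and
scaled by alpha = 3000. By default alpha is normalized by the pixel count
(alpha_eff = alpha / (H*W)), giving sub-pixel-to-few-pixel displacements at
typical working resolutions; the literal un-normalized scaling is available
via the ``elastic.alpha_mode`` config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Config, RandomSource, RasterImage, ensure_config

__all__ = ["DisplacementField", "random_field", "smooth_field", "warp", "app9"]


@dataclass(frozen=True)
class DisplacementField:
    """Per-pixel horizontal (dx) and vertical (dy) displacements in pixels."""

    dx: np.ndarray
    dy: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        dx = np.asarray(self.dx, dtype=np.float64)
        dy = np.asarray(self.dy, dtype=np.float64)
        if dx.shape != dy.shape or dx.ndim != 2:
            raise ValueError("dx and dy must be 2-D arrays of equal shape")
        if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dy))):
            raise ValueError("displacement field contains non-finite values")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape  # type: ignore[return-value]

    def with_alpha(self, alpha: float) -> "DisplacementField":
        return DisplacementField(self.dx, self.dy, alpha)


def random_field(shape: tuple[int, int], rng: RandomSource) -> DisplacementField:
    """Unit-scale field with every entry i.i.d. Uniform[-1, 1]."""
    dx = rng.uniform(-1.0, 1.0, shape)
    dy = rng.uniform(-1.0, 1.0, shape)
    return DisplacementField(dx, dy, alpha=1.0)


def _disk_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = (xx**2 + yy**2 <= r**2).astype(np.float64)
    return k / k.sum()


def _gauss_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _log_kernel(size: int, sigma: float) -> np.ndarray:
    # Laplacian-of-Gaussian, normalized to sum exactly to zero
    ax = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2 * sigma**2))
    g /= g.sum()
    h = g * (r2 - 2 * sigma**2) / sigma**4
    return h - h.mean()


def smooth_field(
    f: DisplacementField, kind: str, config: Config | None = None
) -> DisplacementField:
    """Low-pass filter both components with the chosen kernel.

    Kinds: ``disk`` (circular averaging), ``gaussian``, ``log``
    (Laplacian of Gaussian; zero-sum, so constants map to zero).
    Symmetric boundary padding; shape preserved.
    """
    cfg = ensure_config(config)
    if kind == "disk":
        kernel = _disk_kernel(cfg.get("elastic.kernels.disk_radius"))
    elif kind == "gaussian":
        kernel = _gauss_kernel(
            cfg.get("elastic.kernels.gauss_size"), cfg.get("elastic.kernels.gauss_sigma")
        )
    elif kind == "log":
        kernel = _log_kernel(
            cfg.get("elastic.kernels.log_size"), cfg.get("elastic.kernels.log_sigma")
        )
    else:
        raise ValueError(f"unknown filter kind {kind!r}; expected disk, gaussian or log")
    dx = ndimage.convolve(f.dx, kernel, mode="reflect")
    dy = ndimage.convolve(f.dy, kernel, mode="reflect")
    return DisplacementField(dx, dy, f.alpha)


def warp(
    image: RasterImage, f: DisplacementField, alpha_mode: str = "per_pixel"
) -> RasterImage:
    """Bilinear warp: output(x, y) samples input at (x + a*dx, y + a*dy).

    ``a`` is f.alpha divided by the pixel count in ``per_pixel`` mode, or
    f.alpha verbatim in ``literal`` mode. Sampling coordinates are clamped to
    the image rectangle, so warping never invents values outside the input's
    range.
    """
    H, W = image.height, image.width
    if f.shape != (H, W):
        raise ValueError(f"field shape {f.shape} != image shape {(H, W)}")
    if alpha_mode == "per_pixel":
        a = f.alpha / (H * W)
    elif alpha_mode == "literal":
        a = f.alpha
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    src_r = np.clip(rows + a * f.dy, 0.0, H - 1)
    src_c = np.clip(cols + a * f.dx, 0.0, W - 1)
    out = np.empty_like(image.pixels)
    for c in range(image.channels):
        out[:, :, c] = ndimage.map_coordinates(
            image.pixels[:, :, c], [src_r, src_c], order=1, mode="nearest"
        )
    return RasterImage(np.clip(out, 0.0, 1.0), image.colorspace)


def app9(image: RasterImage, rng: RandomSource, config: Config | None = None) -> list[RasterImage]:
    """Six elastic deformations: three raw-field warps, three filtered-field warps."""
    cfg = ensure_config(config)
    mode = cfg.get("elastic.alpha_mode")
    shape = (image.height, image.width)
    outs = []
    for alpha in cfg.get("elastic.alphas_raw"):
        outs.append(warp(image, random_field(shape, rng).with_alpha(float(alpha)), mode))
    alpha_f = float(cfg.get("elastic.alpha_filtered"))
    for kind in ("disk", "gaussian", "log"):
        f = smooth_field(random_field(shape, rng), kind, cfg).with_alpha(alpha_f)
        outs.append(warp(image, f, mode))
    return outs
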