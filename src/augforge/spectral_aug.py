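"""Transform-domain augmenters: DWT-coefficient perturbation (App10) and
constant-Q-transform-coefficient perturbation (App11).

App10 decomposes each channel with a single-level db1 (Haar) wavelet analysis
into approximation (cA) and detail (cH, cV, cD) subbands, perturbs the
coefficients — random zeroing, a single additive constant tied to the channel
spread, or element swaps with same-class peers — and inverts. A 227×227
channel yields four 114×114 coefficient matrices.

App11 treats each image column as a 1-D signal and analyzes it with a
constant-Q filter bank: geometrically spaced center frequencies (a fixed
number of bins per octave) with window lengths inversely proportional to
frequency, plus a DC band. Analysis is a linear operator (one windowed complex
kernel per bin/frame pair); synthesis uses its pseudo-inverse, which makes the
unperturbed round trip exact to numerical precision. The same three
perturbations act on the complex coefficients, then the inverse transform and
the real part are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .core_io import (
    Config,
    LabeledImageSet,
    RandomSource,
    RasterImage,
    ensure_config,
    sample_peers,
)

__all__ = [
    "WaveletCoefficients",
    "CQTKernel",
    "CQTStack",
    "dwt_forward",
    "dwt_inverse",
    "perturb_wavelet",
    "app10",
    "cqt_forward",
    "cqt_inverse",
    "perturb_cqt",
    "app11",
]


# ---------------------------------------------------------------------------
# single-level db1 DWT
# ---------------------------------------------------------------------------

_DWT_MODE = "symmetric"  # half-point symmetric extension; 227 -> 114 per side


@dataclass(frozen=True)
class WaveletCoefficients:
    """Single-level db1 subbands of one channel: approximation cA and the
    horizontal / vertical / diagonal details cH, cV, cD."""

    cA: np.ndarray
    cH: np.ndarray
    cV: np.ndarray
    cD: np.ndarray
    wavelet: str = "db1"

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cA, self.cH, self.cV, self.cD)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cA.shape  # type: ignore[return-value]

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.cA, self.cH, self.cV, self.cD)


def dwt_forward(channel: np.ndarray, wavelet: str = "db1") -> WaveletCoefficients:
    """Single-level separable wavelet analysis of a 2-D channel.

    Output subbands have side ceil(n/2) per axis (227 -> 114).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or min(channel.shape) < 2:
        raise ValueError("channel must be 2-D with both sides >= 2")
    cA, (cH, cV, cD) = pywt.dwt2(channel, wavelet, mode=_DWT_MODE)
    return WaveletCoefficients(cA, cH, cV, cD, wavelet)


def dwt_inverse(coeffs: WaveletCoefficients, target_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`dwt_forward`, cropped to ``target_shape``.

    Exact (<= 1e-10) for unperturbed coefficients.
    """
    rec = pywt.idwt2((coeffs.cA, (coeffs.cH, coeffs.cV, coeffs.cD)), coeffs.wavelet, mode=_DWT_MODE)
    H, W = target_shape
    if rec.shape[0] < H or rec.shape[1] < W:
        raise ValueError(f"cannot crop reconstruction {rec.shape} to {target_shape}")
    return rec[:H, :W]


def perturb_wavelet(
    coeffs: WaveletCoefficients,
    mode: str,
    rng: RandomSource,
    p_zero: float = 0.5,
    channel_std: float | None = None,
    peers: list[WaveletCoefficients] | None = None,
    p_swap: float = 0.05,
) -> WaveletCoefficients:
    """Perturb all four subbands with one operator.

    ``zero``: each element independently zeroed with probability ``p_zero``.
    ``additive``: a single constant c = channel_std + Uniform(-0.5, 0.5) is
    added to every element of every subband.
    ``swap``: each element replaced, with probability ``p_swap``, by the
    matching element of a uniformly chosen peer's matching subband.
    """
    if mode == "zero":
        out = []
        for m in coeffs.bands():
            keep = rng.random(m.shape) >= p_zero
            out.append(m * keep)
        return WaveletCoefficients(*out, wavelet=coeffs.wavelet)
    if mode == "additive":
        if channel_std is None:
            raise ValueError("additive mode needs channel_std")
        c = channel_std + float(rng.uniform(-0.5, 0.5))
        return WaveletCoefficients(*(m + c for m in coeffs.bands()), wavelet=coeffs.wavelet)
    if mode == "swap":
        if not peers:
            raise ValueError("swap mode needs peer coefficient sets")
        for peer in peers:
            if peer.shape != coeffs.shape:
                raise ValueError("peer subband shape mismatch")
        out = []
        for b, m in enumerate(coeffs.bands()):
            peer_mats = np.stack([peer.bands()[b] for peer in peers])
            hit = rng.random(m.shape) < p_swap
            which = rng.integers(0, len(peers), size=m.shape)
            idx = (which,) + tuple(np.indices(m.shape))
            out.append(np.where(hit, peer_mats[idx], m))
        return WaveletCoefficients(*out, wavelet=coeffs.wavelet)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def app10(
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
) -> list[RasterImage]:
    """Three wavelet-perturbed variants, one per perturbation mode.

    Channels are analyzed, perturbed and inverted independently; the additive
    constant uses each channel's own standard deviation; swap peers are drawn
    from the image's class.
    """
    cfg = ensure_config(config)
    wavelet = cfg.get("spectral.wavelet")
    p_zero = cfg.get("spectral.p_zero")
    p_swap = cfg.get("spectral.p_swap")
    peers = sample_peers(dataset, label, 5, rng, exclude=image)
    shape = (image.height, image.width)
    outputs = []
    for mode in ("zero", "additive", "swap"):
        chans = []
        for c in range(image.channels):
            ch = image.channel(c)
            coeffs = dwt_forward(ch, wavelet)
            if mode == "swap":
                peer_coeffs = [dwt_forward(p.channel(c), wavelet) for p in peers]
                pert = perturb_wavelet(coeffs, "swap", rng, peers=peer_coeffs, p_swap=p_swap)
            elif mode == "additive":
                pert = perturb_wavelet(coeffs, "additive", rng, channel_std=float(np.std(ch)))
            else:
                pert = perturb_wavelet(coeffs, "zero", rng, p_zero=p_zero)
            chans.append(dwt_inverse(pert, shape))
        outputs.append(RasterImage(np.clip(np.stack(chans, axis=-1), 0.0, 1.0), image.colorspace))
    return outputs


# ---------------------------------------------------------------------------
# constant-Q transform (per image column)
# ---------------------------------------------------------------------------

_MIN_COLUMN_LENGTH = 8


class CQTKernel:
    """Constant-Q analysis/synthesis operator for 1-D signals of fixed length.

    Center frequencies run geometrically from 2/n cycles/sample to Nyquist
    with ``bins_per_octave`` bins per octave, preceded by a DC band. Each
    (bin, frame) atom is a Hann-windowed complex exponential whose window
    length is inversely proportional to its frequency (constant Q), centered
    on one of ``n_frames`` uniformly spaced time frames. The atoms stacked
    row-wise form the analysis matrix K; synthesis solves the least-squares
    problem via pinv(K), which is an exact left inverse because the atoms span
    the signal space.
    """

    _cache: dict[tuple[int, int, int], "CQTKernel"] = {}

    def __init__(self, length: int, bins_per_octave: int = 12, n_frames: int | None = None):
        if length < _MIN_COLUMN_LENGTH:
            raise ValueError(
                f"signal length {length} below minimum support {_MIN_COLUMN_LENGTH}"
            )
        self.length = int(length)
        self.bins_per_octave = int(bins_per_octave)
        self.n_frames = int(n_frames) if n_frames is not None else max(4, self.bins_per_octave)
        f_min = 2.0 / self.length
        n_octaves = np.log2(0.5 / f_min)
        n_ladder = int(np.floor(n_octaves * self.bins_per_octave)) + 1
        freqs = f_min * 2.0 ** (np.arange(n_ladder) / self.bins_per_octave)
        self.frequencies = np.concatenate([[0.0], freqs])
        self.n_bins = self.frequencies.size
        q = 1.0 / (2.0 ** (1.0 / self.bins_per_octave) - 1.0)
        centers = (np.arange(self.n_frames) + 0.5) * self.length / self.n_frames
        t = np.arange(self.length)
        rows = []
        for f in self.frequencies:
            win_len = self.length if f == 0.0 else min(self.length, int(np.ceil(q / f)))
            for c in centers:
                d = t - c
                w = np.where(
                    np.abs(d) <= win_len / 2.0,
                    0.5 * (1.0 + np.cos(2.0 * np.pi * d / win_len)),
                    0.0,
                )
                rows.append(w * np.exp(-2j * np.pi * f * d))
        self._K = np.asarray(rows)  # (n_bins * n_frames, length)
        self._K_pinv: np.ndarray | None = None

    @classmethod
    def for_length(cls, length: int, bins_per_octave: int = 12) -> "CQTKernel":
        key = (int(length), int(bins_per_octave), -1)
        if key not in cls._cache:
            cls._cache[key] = cls(length, bins_per_octave)
        return cls._cache[key]

    @property
    def block_shape(self) -> tuple[int, int]:
        return (self.n_bins, self.n_frames)

    def forward(self, signal: np.ndarray) -> np.ndarray:
        signal = np.asarray(signal, dtype=np.float64)
        if signal.shape != (self.length,):
            raise ValueError(f"expected signal of length {self.length}")
        return (self._K @ signal).reshape(self.n_bins, self.n_frames)

    def inverse(self, block: np.ndarray) -> np.ndarray:
        if block.shape != self.block_shape:
            raise ValueError(f"expected coefficient block {self.block_shape}")
        if self._K_pinv is None:
            self._K_pinv = np.linalg.pinv(self._K)
        return (self._K_pinv @ block.ravel()).real


@dataclass(frozen=True)
class CQTStack:
    """One constant-Q coefficient block per image column, plus the kernel
    needed for exact inversion."""

    blocks: tuple[np.ndarray, ...]
    kernel: CQTKernel = field(repr=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty coefficient stack")
        shapes = {b.shape for b in self.blocks}
        if shapes != {self.kernel.block_shape}:
            raise ValueError(f"block shapes {shapes} != kernel {self.kernel.block_shape}")

    def __len__(self) -> int:
        return len(self.blocks)


def cqt_forward(
    channel: np.ndarray, bins_per_octave: int = 12, axis: str = "columns"
) -> CQTStack:
    """Constant-Q analysis of every column (or row) of a channel as a 1-D signal."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("channel must be 2-D")
    if axis == "rows":
        channel = channel.T
    elif axis != "columns":
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")
    kernel = CQTKernel.for_length(channel.shape[0], bins_per_octave)
    blocks = tuple(kernel.forward(channel[:, j]) for j in range(channel.shape[1]))
    return CQTStack(blocks, kernel)


def cqt_inverse(stack: CQTStack, target_shape: tuple[int, int], axis: str = "columns") -> np.ndarray:
    """Column-wise synthesis; exact shape restoration."""
    H, W = target_shape
    n_cols = W if axis == "columns" else H
    n_len = H if axis == "columns" else W
    if len(stack) != n_cols:
        raise ValueError(f"stack has {len(stack)} blocks, target needs {n_cols}")
    if stack.kernel.length != n_len:
        raise ValueError("kernel length does not match target shape")
    cols = np.stack([stack.kernel.inverse(b) for b in stack.blocks], axis=1)
    return cols if axis == "columns" else cols.T


def perturb_cqt(
    stack: CQTStack,
    mode: str,
    rng: RandomSource,
    p_zero: float = 0.5,
    channel_std: float | None = None,
    peers: list[CQTStack] | None = None,
    p_swap: float = 0.05,
    domain: str = "complex",
) -> CQTStack:
    """Perturb the complex coefficients of every block.

    ``zero`` and ``swap`` act on complex values as units; ``additive`` adds
    the constant c = channel_std + Uniform(-0.5, 0.5) to the real part of
    every coefficient (``domain='magnitude'`` scales magnitudes instead,
    preserving phase).
    """
    shape = stack.kernel.block_shape
    if mode == "zero":
        out = []
        for b in stack.blocks:
            keep = rng.random(shape) >= p_zero
            out.append(b * keep)
        return CQTStack(tuple(out), stack.kernel)
    if mode == "additive":
        if channel_std is None:
            raise ValueError("additive mode needs channel_std")
        c = channel_std + float(rng.uniform(-0.5, 0.5))
        if domain == "complex":
            return CQTStack(tuple(b + c for b in stack.blocks), stack.kernel)
        if domain == "magnitude":
            out = []
            for b in stack.blocks:
                mag = np.abs(b)
                phase = np.where(mag > 0, b / np.where(mag > 0, mag, 1.0), 1.0)
                out.append(np.maximum(mag + c, 0.0) * phase)
            return CQTStack(tuple(out), stack.kernel)
        raise ValueError(f"unknown perturbation domain {domain!r}")
    if mode == "swap":
        if not peers:
            raise ValueError("swap mode needs peer stacks")
        for peer in peers:
            if len(peer) != len(stack) or peer.kernel.block_shape != shape:
                raise ValueError("peer stack shape mismatch")
        out = []
        for j, b in enumerate(stack.blocks):
            peer_blocks = np.stack([peer.blocks[j] for peer in peers])
            hit = rng.random(shape) < p_swap
            which = rng.integers(0, len(peers), size=shape)
            idx = (which,) + tuple(np.indices(shape))
            out.append(np.where(hit, peer_blocks[idx], b))
        return CQTStack(tuple(out), stack.kernel)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def app11(
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
) -> list[RasterImage]:
    """Three constant-Q-perturbed variants, one per perturbation mode."""
    cfg = ensure_config(config)
    bpo = cfg.get("spectral.cqt_bins_per_octave")
    axis = cfg.get("spectral.cqt_axis")
    domain = cfg.get("spectral.cqt_perturb_domain")
    p_zero = cfg.get("spectral.p_zero")
    p_swap = cfg.get("spectral.p_swap")
    peers = sample_peers(dataset, label, 5, rng, exclude=image)
    shape = (image.height, image.width)
    outputs = []
    for mode in ("zero", "additive", "swap"):
        chans = []
        for c in range(image.channels):
            ch = image.channel(c)
            stack = cqt_forward(ch, bpo, axis)
            if mode == "swap":
                peer_stacks = [cqt_forward(p.channel(c), bpo, axis) for p in peers]
                pert = perturb_cqt(stack, "swap", rng, peers=peer_stacks, p_swap=p_swap)
            elif mode == "additive":
                pert = perturb_cqt(
                    stack, "additive", rng, channel_std=float(np.std(ch)), domain=domain
                )
            else:
                pert = perturb_cqt(stack, "zero", rng, p_zero=p_zero)
            chans.append(cqt_inverse(pert, shape, axis))
        outputs.append(RasterImage(np.clip(np.stack(chans, axis=-1), 0.0, 1.0), image.colorspace))
    return outputs
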