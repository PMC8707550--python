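"""Subspace augmenters: PCA-coefficient perturbation (App4) and DCT-coefficient
perturbation with DC preservation (App5).

Both methods map a channel into a linear basis, perturb the coefficient vector
with one of three operators — random zeroing, bounded uniform noise scaled by
the coefficient spread, or element swaps with same-class peers — and map back.
The PCA basis is fit on the training data only; the DCT is the orthonormal
2-D type-II transform and its DC (0,0) coefficient is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from sklearn.decomposition import PCA

from .core_io import (
    Config,
    LabeledImageSet,
    RandomSource,
    RasterImage,
    ensure_config,
    sample_peers,
)

__all__ = [
    "SubspaceBasis",
    "CoefficientVector",
    "fit_pca",
    "project",
    "reconstruct",
    "dct_vector",
    "dct_image_channel",
    "perturb_zero",
    "perturb_noise",
    "perturb_swap",
    "app4",
    "app5",
]


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal PCA basis of vectorized training channels."""

    mean: np.ndarray        # (D,)
    components: np.ndarray  # (n_components, D), rows orthonormal
    eigenvalues: np.ndarray
    shape: tuple[int, int]  # H, W of the channel plane

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class CoefficientVector:
    """One channel expressed in the active basis.

    ``dc_index`` flags the zero-frequency term in DCT mode (None for PCA);
    the flagged element is exempt from every perturbation operator.
    """

    values: np.ndarray
    dc_index: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", vals)
        if self.dc_index is not None and not (0 <= self.dc_index < vals.size):
            raise ValueError("dc_index out of range")

    def _mutable_mask(self) -> np.ndarray:
        mask = np.ones(self.values.size, dtype=bool)
        if self.dc_index is not None:
            mask[self.dc_index] = False
        return mask


# ---------------------------------------------------------------------------
# PCA basis
# ---------------------------------------------------------------------------

def fit_pca(training: LabeledImageSet, channel: int = 0) -> SubspaceBasis:
    """Fit a PCA basis to one channel of the training images.

    Channels are vectorized and mean-centered; all components with eigenvalue
    above 1e-10 of the leading one are kept, which makes reconstruction of the
    training images themselves near-lossless. The sign of each component is
    normalized so its largest-magnitude entry is positive, making the basis
    invariant to training-set permutation.
    """
    if len(training) < 2:
        raise ValueError("PCA basis needs at least 2 training images")
    shapes = {img.channel(channel).shape for img, _ in training}
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes in training set: {sorted(shapes)}")
    H, W = next(iter(shapes))
    X = np.stack([img.channel(channel).ravel() for img, _ in training])
    pca = PCA(svd_solver="full")
    pca.fit(X)
    ev = pca.explained_variance_
    if ev.size and ev[0] > 0:
        # relative cutoff keeps reconstruction near-lossless; absolute floor
        # drops pure round-off directions (e.g. identical training images)
        keep = ev > np.maximum(1e-10 * ev[0], 1e-12)
    else:
        keep = np.zeros(ev.size, dtype=bool)
    comps = pca.components_[keep]
    # deterministic sign: largest-magnitude entry of each component positive
    if comps.size:
        flip = comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)] < 0
        comps = np.where(flip[:, None], -comps, comps)
    return SubspaceBasis(
        mean=pca.mean_.copy(),
        components=comps,
        eigenvalues=ev[keep].copy(),
        shape=(H, W),
    )


def project(basis: SubspaceBasis, channel: np.ndarray) -> CoefficientVector:
    if channel.shape != basis.shape:
        raise ValueError(f"channel shape {channel.shape} != basis shape {basis.shape}")
    scores = basis.components @ (channel.ravel() - basis.mean)
    return CoefficientVector(scores, dc_index=None)


def reconstruct(basis: SubspaceBasis, v: CoefficientVector) -> np.ndarray:
    if v.values.size != basis.n_components:
        raise ValueError("coefficient length does not match basis rank")
    flat = basis.mean + v.values @ basis.components
    return flat.reshape(basis.shape)


# ---------------------------------------------------------------------------
# DCT basis (orthonormal 2-D type-II)
# ---------------------------------------------------------------------------

def dct_image_channel(channel: np.ndarray) -> np.ndarray:
    return sfft.dctn(channel, norm="ortho")


def idct_image_channel(coeffs: np.ndarray) -> np.ndarray:
    return sfft.idctn(coeffs, norm="ortho")


def dct_vector(channel: np.ndarray) -> CoefficientVector:
    """Flatten the 2-D DCT of a channel, flagging the (0, 0) DC term."""
    return CoefficientVector(dct_image_channel(channel).ravel(), dc_index=0)


def dct_unvector(v: CoefficientVector, shape: tuple[int, int]) -> np.ndarray:
    return idct_image_channel(v.values.reshape(shape))


# ---------------------------------------------------------------------------
# perturbation operators
# ---------------------------------------------------------------------------

def perturb_zero(v: CoefficientVector, p: float, rng: RandomSource) -> CoefficientVector:
    """Zero each non-DC element independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    out = v.values.copy()
    hit = (rng.random(out.size) < p) & v._mutable_mask()
    out[hit] = 0.0
    return CoefficientVector(out, v.dc_index)


def perturb_noise(v: CoefficientVector, rng: RandomSource) -> CoefficientVector:
    """Add bounded uniform noise of amplitude std(values)/2 to each non-DC element.

    Each element receives (u - 0.5) * std(values)/2 with u ~ Uniform(0, 1), so a
    constant vector (zero spread) passes through unchanged.
    """
    amp = float(np.std(v.values)) / 2.0
    out = v.values.copy()
    mask = v._mutable_mask()
    out[mask] = out[mask] + (rng.random(int(mask.sum())) - 0.5) * amp
    return CoefficientVector(out, v.dc_index)


def perturb_swap(
    v: CoefficientVector,
    peers: list[CoefficientVector],
    p: float,
    rng: RandomSource,
) -> CoefficientVector:
    """Replace each non-DC element, with probability ``p``, by the same-index
    element of a uniformly chosen peer vector."""
    if not peers:
        raise ValueError("swap perturbation needs at least one peer vector")
    n = v.values.size
    for peer in peers:
        if peer.values.size != n:
            raise ValueError("peer coefficient length mismatch")
    peer_mat = np.stack([peer.values for peer in peers])  # (k, n)
    hit = (rng.random(n) < p) & v._mutable_mask()
    which = rng.integers(0, len(peers), size=n)
    out = v.values.copy()
    out[hit] = peer_mat[which[hit], np.nonzero(hit)[0]]
    return CoefficientVector(out, v.dc_index)


# ---------------------------------------------------------------------------
# App4 / App5
# ---------------------------------------------------------------------------

def app4(
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    bases: list[SubspaceBasis],
    rng: RandomSource,
    config: Config | None = None,
) -> list[RasterImage]:
    """Three PCA-perturbed variants: one per perturbation operator.

    Every channel is projected onto its training-set PCA basis, perturbed and
    reconstructed; swap peers are drawn from the image's class.
    """
    cfg = ensure_config(config)
    if len(bases) != image.channels:
        raise ValueError("need one PCA basis per channel")
    p_zero = cfg.get("sub.p_zero")
    p_swap = cfg.get("sub.p_swap")
    n_peers = cfg.get("sub.n_peers")
    peers = sample_peers(dataset, label, n_peers, rng, exclude=image)
    outputs = []
    for mode in ("zero", "noise", "swap"):
        chans = []
        for c in range(image.channels):
            v = project(bases[c], image.channel(c))
            if mode == "zero":
                v2 = perturb_zero(v, p_zero, rng)
            elif mode == "noise":
                v2 = perturb_noise(v, rng)
            else:
                peer_vs = [project(bases[c], pimg.channel(c)) for pimg in peers]
                v2 = perturb_swap(v, peer_vs, p_swap, rng)
            chans.append(reconstruct(bases[c], v2))
        outputs.append(RasterImage(np.clip(np.stack(chans, axis=-1), 0.0, 1.0), image.colorspace))
    return outputs


def app5(
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
) -> list[RasterImage]:
    """Three DCT-perturbed variants; the DC coefficient is never changed."""
    cfg = ensure_config(config)
    p_zero = cfg.get("sub.p_zero")
    p_swap = cfg.get("sub.p_swap")
    n_peers = cfg.get("sub.n_peers")
    peers = sample_peers(dataset, label, n_peers, rng, exclude=image)
    shape = (image.height, image.width)
    outputs = []
    for mode in ("zero", "noise", "swap"):
        chans = []
        for c in range(image.channels):
            v = dct_vector(image.channel(c))
            if mode == "zero":
                v2 = perturb_zero(v, p_zero, rng)
            elif mode == "noise":
                v2 = perturb_noise(v, rng)
            else:
                peer_vs = [dct_vector(pimg.channel(c)) for pimg in peers]
                v2 = perturb_swap(v, peer_vs, p_swap, rng)
            chans.append(dct_unvector(v2, shape))
        outputs.append(RasterImage(np.clip(np.stack(chans, axis=-1), 0.0, 1.0), image.colorspace))
    return outputs
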