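"""Core domain types, seeded randomness, image-set I/O and synthetic fixtures.

Images are carried internally as float64 arrays in [0, 1]; conversion to and
from 8-bit happens only at the disk boundary so that the transform-domain
augmenters (PCA, DCT, DWT, CQT) operate in real arithmetic and a single
clip-at-the-end policy keeps every augmenter composable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RasterImage",
    "LabeledImageSet",
    "RandomSource",
    "AugmentationMethod",
    "METHODS",
    "METHOD_ORDER",
    "PeerShortageError",
    "Config",
    "DEFAULT_CONFIG",
    "load_config",
    "read_image_set",
    "write_image_set",
    "make_fixtures",
    "sample_peers",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RasterImage:
    """An H×W×C intensity image, values stored as reals (nominally in [0, 1]).

    ``C`` is 1 (grayscale) or 3 (linear RGB assumed). Augmenters preserve H, W
    and C; intermediate values may leave [0, 1] and are clipped by the method
    that produced them before being returned.
    """

    pixels: np.ndarray
    colorspace: str = "rgb"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"expected H×W×C pixel array, got shape {px.shape}")
        if px.shape[2] not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "pixels", px)
        tag = "gray" if px.shape[2] == 1 else self.colorspace
        object.__setattr__(self, "colorspace", tag)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def clipped(self) -> "RasterImage":
        return RasterImage(np.clip(self.pixels, 0.0, 1.0), self.colorspace)

    def channel(self, i: int) -> np.ndarray:
        return self.pixels[:, :, i]


class PeerShortageError(ValueError):
    """Raised when a class-conditional method finds no same-class peer."""


@dataclass(frozen=True)
class LabeledImageSet:
    """An ordered collection of (image, class label) pairs.

    Supplies same-class peers for the class-conditional augmenters. All
    images must share a channel count.
    """

    items: tuple[tuple[RasterImage, str], ...]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        labels = sorted({lab for _, lab in items})
        declared = tuple(self.classes) if self.classes else tuple(labels)
        missing = set(labels) - set(declared)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in declared classes")
        object.__setattr__(self, "classes", declared)
        chans = {img.channels for img, _ in items}
        if len(chans) > 1:
            raise ValueError(f"mixed channel counts in set: {sorted(chans)}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[tuple[RasterImage, str]]:
        return iter(self.items)

    def __getitem__(self, i: int) -> tuple[RasterImage, str]:
        return self.items[i]

    @property
    def channels(self) -> int:
        if not self.items:
            raise ValueError("empty image set has no channel count")
        return self.items[0][0].channels

    def images(self) -> list[RasterImage]:
        return [img for img, _ in self.items]

    def labels(self) -> list[str]:
        return [lab for _, lab in self.items]

    def class_members(self, label: str) -> list[RasterImage]:
        return [img for img, lab in self.items if lab == label]


class RandomSource:
    """Seeded random stream with reproducible per-image forking.

    Identical seed plus identical call sequence gives bit-identical draws;
    ``spawn`` forks statistically independent child streams so per-image
    work can be parallelised without changing outputs.
    """

    def __init__(self, seed: int | np.random.SeedSequence):
        if isinstance(seed, np.random.SeedSequence):
            self._seq = seed
        else:
            self._seq = np.random.SeedSequence(int(seed))
        self._rng = np.random.default_rng(self._seq)

    @property
    def generator(self) -> np.random.Generator:
        return self._rng

    def spawn(self, n: int) -> list["RandomSource"]:
        return [RandomSource(s) for s in self._seq.spawn(n)]

    def uniform(self, low: float = 0.0, high: float = 1.0, size=None):
        return self._rng.uniform(low, high, size)

    def random(self, size=None):
        return self._rng.random(size)

    def integers(self, low: int, high: int | None = None, size=None):
        return self._rng.integers(low, high, size)

    def choice(self, a, size=None, replace: bool = True):
        return self._rng.choice(a, size=size, replace=replace)


@dataclass(frozen=True)
class AugmentationMethod:
    """Descriptor of one augmentation protocol App1–App11."""

    id: str
    images_per_input: int
    requires_color: bool
    requires_peers: bool


METHOD_ORDER: tuple[str, ...] = tuple(f"App{i}" for i in range(1, 12))

# images_per_input: number of artificial images each method adds per original
METHODS: dict[str, AugmentationMethod] = {
    m.id: m
    for m in (
        AugmentationMethod("App1", 3, False, False),
        AugmentationMethod("App2", 6, False, False),
        AugmentationMethod("App3", 4, False, False),
        AugmentationMethod("App4", 3, False, True),
        AugmentationMethod("App5", 3, False, True),
        AugmentationMethod("App6", 3, True, False),
        AugmentationMethod("App7", 7, True, False),
        AugmentationMethod("App8", 2, True, True),
        AugmentationMethod("App9", 6, False, False),
        AugmentationMethod("App10", 3, False, True),
        AugmentationMethod("App11", 3, False, True),
    )
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, object] = {
    # geometric
    "geo.scale_range": (1.0, 2.0),
    "geo.rot_range": (-10.0, 10.0),
    "geo.shift_range": (0.0, 5.0),
    "geo.shear_range": (0.0, 30.0),
    "geo.reflect_prob": 0.5,
    "geo.random_shift_sign": False,
    # subspace
    "sub.p_zero": 0.5,
    "sub.p_swap": 0.05,
    "sub.n_peers": 5,
    # photometric
    "photo.contrast_a_range": (0, 50),
    "photo.contrast_b_range": (205, 255),
    "photo.shift_range": (-30, 30),
    "photo.jitter.hue": (0.05, 0.15),
    "photo.jitter.saturation": (-0.4, -0.1),
    "photo.jitter.brightness": (-0.3, -0.1),
    "photo.jitter.contrast": (1.2, 1.4),
    "photo.jitter.blur_sigma": (1.0, 6.0),
    "photo.jitter.sharpen_radius": 1.0,
    "photo.jitter.sharpen_strength": 2.0,
    "photo.sharpen_literal": False,
    # elastic
    "elastic.alphas_raw": (7000.0, 1000.0, 13000.0),
    "elastic.alpha_filtered": 3000.0,
    "elastic.alpha_mode": "per_pixel",  # or "literal"
    "elastic.kernels.disk_radius": 5,
    "elastic.kernels.gauss_size": 7,
    "elastic.kernels.gauss_sigma": 1.5,
    "elastic.kernels.log_size": 7,
    "elastic.kernels.log_sigma": 0.5,
    # spectral
    "spectral.wavelet": "db1",
    "spectral.p_zero": 0.5,
    "spectral.p_swap": 0.05,
    "spectral.cqt_bins_per_octave": 12,
    "spectral.cqt_axis": "columns",
    "spectral.cqt_perturb_domain": "complex",  # or "magnitude"
}


class Config:
    """Flat dotted-key configuration holding every tunable of the augmenters."""

    def __init__(self, overrides: dict[str, object] | None = None):
        self._values = dict(DEFAULT_CONFIG)
        if overrides:
            for key, val in overrides.items():
                if key not in DEFAULT_CONFIG:
                    raise KeyError(f"unknown config key: {key!r}")
                self._values[key] = val

    def get(self, key: str):
        return self._values[key]

    def with_overrides(self, **pairs) -> "Config":
        out = Config()
        out._values = dict(self._values)
        for key, val in pairs.items():
            dotted = key.replace("__", ".")
            if dotted not in DEFAULT_CONFIG:
                raise KeyError(f"unknown config key: {dotted!r}")
            out._values[dotted] = val
        return out

    def as_dict(self) -> dict[str, object]:
        return dict(self._values)


def load_config(path: str | Path) -> Config:
    """Load a flat key-value config file (YAML mapping of dotted keys)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key: value mapping")
    clean: dict[str, object] = {}
    for key, val in data.items():
        clean[str(key)] = tuple(val) if isinstance(val, list) else val
    return Config(clean)


def ensure_config(config: Config | None) -> Config:
    return config if config is not None else Config()


# ---------------------------------------------------------------------------
# peer sampling (shared by the class-conditional methods)
# ---------------------------------------------------------------------------

def sample_peers(
    dataset: LabeledImageSet,
    label: str,
    n: int,
    rng: RandomSource,
    exclude: RasterImage | None = None,
) -> list[RasterImage]:
    """Draw ``n`` same-class peer images, excluding the query image itself.

    With at least ``n`` other members the draw is without replacement; with
    1 ≤ k < n members the ``n`` peers are drawn with replacement from the k;
    an empty peer pool raises :class:`PeerShortageError`.
    """
    pool = [
        img
        for img, lab in dataset
        if lab == label and (exclude is None or img.pixels is not exclude.pixels)
    ]
    if not pool:
        raise PeerShortageError(f"class {label!r} has no other member to draw peers from")
    replace = len(pool) < n
    idx = rng.choice(len(pool), size=n, replace=replace)
    return [pool[i] for i in np.atleast_1d(idx)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def _load_one(path: Path) -> RasterImage:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"unreadable image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    return RasterImage(arr)


def read_image_set(path: str | Path) -> LabeledImageSet:
    """Read a labeled image set from a folder-per-class directory or a CSV manifest.

    Item order is deterministic: classes and filenames sorted lexically for a
    directory; manifest row order for a CSV. Pixel values are normalized to
    [0, 1]; grayscale files yield C=1 images (never promoted to RGB).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    items: list[tuple[RasterImage, str]] = []
    if path.is_file():
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"filepath", "label"} - set(reader.fieldnames):
                raise ValueError("manifest must have columns: filepath,label")
            for row in reader:
                fp = path.parent / row["filepath"]
                items.append((_load_one(fp), row["label"]))
    else:
        class_dirs = sorted(p for p in path.iterdir() if p.is_dir())
        if not class_dirs:
            raise ValueError(f"no class folders under {path}")
        for cdir in class_dirs:
            files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
            if not files:
                raise ValueError(f"class folder {cdir.name!r} contains no images")
            for fp in files:
                items.append((_load_one(fp), cdir.name))
    return LabeledImageSet(tuple(items))


def write_image_set(
    dataset: LabeledImageSet, path: str | Path, overwrite: bool = False
) -> Path:
    """Write folder-per-class 8-bit PNGs plus a CSV manifest; returns the manifest path."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty image set")
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists and is not empty (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    rows: list[tuple[str, str]] = []
    for img, label in dataset:
        counters[label] = counters.get(label, 0) + 1
        cdir = path / label
        cdir.mkdir(exist_ok=True)
        name = f"{label}_{counters[label]:05d}.png"
        px = np.clip(img.pixels, 0.0, 1.0)
        arr8 = np.round(px * 255.0).astype(np.uint8)
        if arr8.shape[2] == 1:
            arr8 = arr8[:, :, 0]
        iio.imwrite(cdir / name, arr8)
        rows.append((f"{label}/{name}", label))
    manifest = path / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filepath", "label"])
        writer.writerows(rows)
    return manifest


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def make_fixtures(
    n_classes: int,
    per_class: int,
    size: tuple[int, int] = (64, 64),
    channels: int = 3,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate a class-structured synthetic image set.

    Each class is a distinct texture family: an oriented sinusoid grating with
    class-specific orientation and spatial frequency (and, for RGB, a
    class-specific per-channel amplitude profile), plus per-image random phase
    and seeded pixel noise. Classes are therefore separable by simple texture
    features while same-class images differ enough for class-conditional
    swaps to be meaningful. Pure function of its arguments.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if per_class < 1:
        raise ValueError("need at least 1 image per class")
    if channels not in (1, 3):
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    H, W = size
    rng = RandomSource(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    items: list[tuple[RasterImage, str]] = []
    for c in range(n_classes):
        theta = np.pi * c / n_classes
        freq = 0.06 + 0.05 * c  # cycles per pixel, distinct per class
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        if channels == 3:
            amp = 0.18 + 0.17 * np.array(
                [((c + k) % 3) / 2.0 for k in range(3)]
            )  # class-specific color profile
        else:
            amp = np.array([0.35])
        label = f"class_{c:02d}"
        for _ in range(per_class):
            phase = rng.uniform(0.0, 2 * np.pi)
            base = np.sin(2 * np.pi * freq * proj + phase)
            px = 0.5 + base[:, :, None] * amp[None, None, :]
            px = px + rng.generator.normal(0.0, 0.05, px.shape)
            items.append((RasterImage(np.clip(px, 0.0, 1.0)), label))
    return LabeledImageSet(tuple(items))
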