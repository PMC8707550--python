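"""Method dispatch: run any App1–App11 augmenter on one image or a whole set."""

from __future__ import annotations

from . import (
    elastic_aug,
    geometric_aug,
    photometric_aug,
    spectral_aug,
    subspace_aug,
)
from .core_io import (
    METHODS,
    Config,
    LabeledImageSet,
    RandomSource,
    RasterImage,
    ensure_config,
)

__all__ = ["augment_image", "augment_set", "fit_app4_bases"]


def fit_app4_bases(dataset: LabeledImageSet) -> list[subspace_aug.SubspaceBasis]:
    """Per-channel PCA bases for App4, fit on the given (training) set."""
    return [subspace_aug.fit_pca(dataset, c) for c in range(dataset.channels)]


def augment_image(
    method_id: str,
    image: RasterImage,
    label: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
    pca_bases: list[subspace_aug.SubspaceBasis] | None = None,
) -> list[RasterImage]:
    """Apply one augmentation method; returns its images_per_input outputs.

    ``dataset`` supplies same-class peers for the class-conditional methods
    and, for App4, the default PCA training data when ``pca_bases`` is not
    passed explicitly.
    """
    if method_id not in METHODS:
        raise ValueError(f"unknown method {method_id!r}")
    method = METHODS[method_id]
    if method.requires_color and image.channels != 3:
        raise ValueError(f"{method_id} requires 3-channel images")
    cfg = ensure_config(config)
    if method_id == "App1":
        return geometric_aug.app1(image, rng, cfg)
    if method_id == "App2":
        return geometric_aug.app2(image, rng, cfg)
    if method_id == "App3":
        return geometric_aug.app3(image, rng, cfg)
    if method_id == "App4":
        bases = pca_bases if pca_bases is not None else fit_app4_bases(dataset)
        return subspace_aug.app4(image, label, dataset, bases, rng, cfg)
    if method_id == "App5":
        return subspace_aug.app5(image, label, dataset, rng, cfg)
    if method_id == "App6":
        return photometric_aug.app6(image, rng, cfg)
    if method_id == "App7":
        return photometric_aug.app7(image, rng, cfg)
    if method_id == "App8":
        return photometric_aug.app8(image, label, dataset, rng, cfg)
    if method_id == "App9":
        return elastic_aug.app9(image, rng, cfg)
    if method_id == "App10":
        return spectral_aug.app10(image, label, dataset, rng, cfg)
    return spectral_aug.app11(image, label, dataset, rng, cfg)


def augment_set(
    method_id: str,
    dataset: LabeledImageSet,
    rng: RandomSource,
    config: Config | None = None,
) -> LabeledImageSet:
    """Augmented images only (no originals), labels inherited from sources.

    Each image gets its own forked random sub-stream, so per-image results are
    independent of processing order.
    """
    method = METHODS[method_id]
    if method.requires_color and dataset.channels != 3:
        raise ValueError(f"{method_id} requires a 3-channel image set")
    bases = fit_app4_bases(dataset) if method_id == "App4" else None
    streams = rng.spawn(len(dataset))
    items = []
    for (image, label), sub in zip(dataset, streams):
        for out in augment_image(method_id, image, label, dataset, sub, config, bases):
            items.append((out, label))
    return LabeledImageSet(tuple(items), dataset.classes)
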