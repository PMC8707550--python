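"""Ensemble harness: per-method training-set assembly, a pluggable classifier
backbone, sum-rule score fusion and the named ensemble configurations.

One classifier is trained per augmentation method on the original images plus
that method's augmented copies; the per-class softmax scores of the members
are summed and the fused prediction is the argmax (ties toward the lowest
class index). Named configurations: ``ensda_all`` fuses one member per
applicable method (the three color methods are dropped for grayscale sets),
``ensda_5`` uses App1–App5, ``ensbase`` / ``ensbase_5`` are same-method
controls fusing eleven / five members all trained on App3, and ``noda`` is a
single member with no augmentation.

The default backbone is a small multilayer-perceptron classifier on
downsampled pixels — sized so a 3-class fixture problem trains in seconds on
one CPU. Any callable with the same signature can be plugged in as the
backbone for full-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.neural_network import MLPClassifier

from .core_io import (
    METHOD_ORDER,
    METHODS,
    AugmentationMethod,
    Config,
    LabeledImageSet,
    RandomSource,
)
from .pipeline import augment_set

__all__ = [
    "ScoreMatrix",
    "EnsembleSpec",
    "TrainConfig",
    "EvaluationReport",
    "build_training_set",
    "applicable_methods",
    "train_member",
    "sum_rule_fusion",
    "predictions",
    "accuracy",
    "evaluate",
    "named_spec",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-sample, per-class classifier scores (post-softmax)."""

    scores: np.ndarray            # (n_samples, n_classes)
    sample_ids: tuple[int, ...]
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 2:
            raise ValueError("scores must be 2-D")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores contain non-finite values")
        if s.shape != (len(self.sample_ids), len(self.class_order)):
            raise ValueError("scores shape disagrees with ids/classes")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "class_order", tuple(self.class_order))


@dataclass(frozen=True)
class EnsembleSpec:
    """A named list of member methods (repetition allowed; empty = no augmentation)."""

    name: str
    members: tuple[str, ...]


@dataclass
class TrainConfig:
    """Backbone training settings. Defaults: batch size 30, learning rate 0.001.

    ``backbone`` is "tiny" (built-in MLP) or a callable
    ``f(train, test, cfg, seed) -> ScoreMatrix`` for user-supplied models.
    """

    backbone: str | Callable = "tiny"
    batch_size: int = 30
    learning_rate: float = 0.001
    epochs: int = 150
    hidden_units: int = 64
    feature_size: tuple[int, int] = (16, 16)
    seed: int = 0


@dataclass(frozen=True)
class EvaluationReport:
    spec_name: str
    fused_accuracy: float
    member_accuracies: tuple[tuple[str, float], ...]  # (member label, accuracy)


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

def build_training_set(
    base: LabeledImageSet,
    method: AugmentationMethod | str,
    rng: RandomSource,
    config: Config | None = None,
) -> LabeledImageSet:
    """Original images plus the method's augmented copies.

    Output size is |base| * (1 + images_per_input); every augmented item
    carries its source's label.
    """
    method_id = method if isinstance(method, str) else method.id
    aug = augment_set(method_id, base, rng, config)
    return LabeledImageSet(tuple(base.items) + tuple(aug.items), base.classes)


def applicable_methods(dataset: LabeledImageSet) -> list[AugmentationMethod]:
    """All eleven methods for RGB sets; the color methods are excluded for
    grayscale sets (they cannot produce meaningful 1-channel variants).
    Order is deterministic App1..App11."""
    gray = dataset.channels == 1
    return [
        METHODS[mid]
        for mid in METHOD_ORDER
        if not (gray and METHODS[mid].requires_color)
    ]


def named_spec(name: str, grayscale: bool = False) -> EnsembleSpec:
    """The named ensemble configurations (case-insensitive)."""
    key = name.lower()
    all_methods = tuple(
        mid for mid in METHOD_ORDER if not (grayscale and METHODS[mid].requires_color)
    )
    table = {
        "ensda_all": all_methods,
        "ensda_5": tuple(METHOD_ORDER[:5]),
        "ensbase": ("App3",) * 11,
        "ensbase_5": ("App3",) * 5,
        "noda": (),
    }
    if key not in table:
        raise ValueError(f"unknown ensemble spec {name!r}; options: {sorted(table)}")
    return EnsembleSpec(key, table[key])


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def _features(dataset: LabeledImageSet, size: tuple[int, int]) -> np.ndarray:
    rows = []
    for img, _ in dataset:
        small = resize(img.pixels, (*size, img.channels), anti_aliasing=True)
        rows.append(small.ravel())
    return np.asarray(rows)


def train_member(
    trainset: LabeledImageSet,
    testset: LabeledImageSet,
    cfg: TrainConfig,
    rng: RandomSource,
) -> tuple[object, ScoreMatrix]:
    """Train one backbone on ``trainset`` and score ``testset``.

    Returns the fitted model and a ScoreMatrix whose rows are softmax class
    scores (each summing to 1). Deterministic for a fixed rng state.
    """
    train_classes = set(trainset.labels())
    missing = set(testset.labels()) - train_classes
    if missing:
        raise ValueError(f"test classes absent from training set: {sorted(missing)}")
    seed = int(rng.integers(0, 2**31 - 1))
    if callable(cfg.backbone):
        return None, cfg.backbone(trainset, testset, cfg, seed)
    if cfg.backbone != "tiny":
        raise ValueError(
            f"unknown backbone {cfg.backbone!r}: pass 'tiny' or a callable "
            "f(train, test, cfg, seed) -> ScoreMatrix"
        )
    X_train = _features(trainset, cfg.feature_size)
    X_test = _features(testset, cfg.feature_size)
    model = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        batch_size=min(cfg.batch_size, len(trainset)),
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.epochs,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_train, trainset.labels())
    class_order = tuple(model.classes_)
    scores = model.predict_proba(X_test)
    return model, ScoreMatrix(scores, tuple(range(len(testset))), class_order)


# ---------------------------------------------------------------------------
# fusion and evaluation
# ---------------------------------------------------------------------------

def sum_rule_fusion(members: Sequence[ScoreMatrix]) -> ScoreMatrix:
    """Elementwise sum of member score matrices (ids and class order must align)."""
    if not members:
        raise ValueError("need at least one member to fuse")
    first = members[0]
    for m in members[1:]:
        if m.sample_ids != first.sample_ids or m.class_order != first.class_order:
            raise ValueError("member score matrices are misaligned")
    total = np.sum([m.scores for m in members], axis=0)
    return ScoreMatrix(total, first.sample_ids, first.class_order)


def predictions(sm: ScoreMatrix) -> list[str]:
    """Argmax per row; ties break toward the lowest class index."""
    return [sm.class_order[i] for i in np.argmax(sm.scores, axis=1)]


def accuracy(sm: ScoreMatrix, true_labels: Sequence[str]) -> float:
    pred = predictions(sm)
    if len(pred) != len(true_labels):
        raise ValueError("label count mismatch")
    return float(np.mean([p == t for p, t in zip(pred, true_labels)]))


def evaluate(
    spec: EnsembleSpec,
    base_train: LabeledImageSet,
    test: LabeledImageSet,
    cfg: TrainConfig,
    rng: RandomSource,
    config: Config | None = None,
) -> EvaluationReport:
    """Train one member per spec entry, fuse by sum rule, report accuracies.

    An empty member list is the no-augmentation baseline: a single model
    trained on the base set alone.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    true_labels = test.labels()
    member_scores: list[ScoreMatrix] = []
    member_rows: list[tuple[str, float]] = []
    if not spec.members:
        _, sm = train_member(base_train, test, cfg, rng)
        member_scores.append(sm)
        member_rows.append(("none", accuracy(sm, true_labels)))
    else:
        streams = rng.spawn(len(spec.members))
        for k, (mid, sub) in enumerate(zip(spec.members, streams)):
            trainset = build_training_set(base_train, mid, sub, config)
            _, sm = train_member(trainset, test, cfg, sub)
            member_scores.append(sm)
            member_rows.append((f"{mid}#{k}", accuracy(sm, true_labels)))
    fused = sum_rule_fusion(member_scores)
    return EvaluationReport(spec.name, accuracy(fused, true_labels), tuple(member_rows))
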