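"""Seeded generator of a complete synthetic grading study.

Real crowd responses for this kind of study are rarely deposited, so the
package carries a first-class simulator with the statistical structure the
downstream analysis assumes: a 100-image corpus (10 severely abnormal, 60
mildly abnormal, 30 normal; 16 images held out for training, 6 of them normal)
and a crowd of annotators in three groups, each annotator described by an
error-model profile:

* ``sens`` / ``spec`` — per-response probability of labeling a nonhealthy
  (resp. healthy) image correctly;
* ``p_detect`` — per-lesion probability of reproducing an expert rectangle;
* ``jitter_sd`` — pixel s.d. of Gaussian noise added to rectangle corners;
* ``scale_sd`` — s.d. of log-normal noise on rectangle size (scaled about the
  rectangle center);
* ``fp_rate`` — expected number (Poisson) of spurious rectangles per image the
  annotator labels nonhealthy.

Lesions are axis-aligned rectangles, so the expert reference and the annotator
input share one geometry.  All randomness flows from a single master seed via
``numpy.random.SeedSequence`` spawn keys: the corpus and every individual
annotator draw from independent substreams, so adding an annotator or a group
never perturbs the responses of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .annotation_data import (
    GROUPS,
    AnnotationRecord,
    ImageTruth,
    Rectangle,
    ValidationError,
)

_CORPUS_KEY = 0
_CROWD_KEY = 1


@dataclass(frozen=True)
class CorpusConfig:
    """Composition and geometry of the synthetic image corpus."""

    n_severe: int = 10
    n_mild: int = 60
    n_normal: int = 30
    n_training: int = 16
    n_training_normal: int = 6
    width: int = 512
    height: int = 512
    # lesion count ranges (inclusive) and side-length ranges in pixels
    mild_lesion_count: tuple[int, int] = (1, 3)
    severe_lesion_count: tuple[int, int] = (3, 6)
    mild_lesion_size: tuple[int, int] = (20, 60)
    severe_lesion_size: tuple[int, int] = (40, 120)

    def __post_init__(self) -> None:
        if self.n_training > self.n_severe + self.n_mild + self.n_normal:
            raise ValidationError("n_training exceeds corpus size")
        if self.n_training_normal > min(self.n_training, self.n_normal):
            raise ValidationError("n_training_normal exceeds n_training or n_normal")
        if self.n_training - self.n_training_normal > self.n_severe + self.n_mild:
            raise ValidationError("not enough abnormal images for the training set")
        for lo, hi in (self.mild_lesion_size, self.severe_lesion_size):
            if lo < 1 or hi < lo:
                raise ValidationError("lesion size range must satisfy 1 <= lo <= hi")
            if hi > self.width or hi > self.height:
                raise ValidationError("lesion larger than image")
        for lo, hi in (self.mild_lesion_count, self.severe_lesion_count):
            if lo < 1 or hi < lo:
                raise ValidationError("lesion count range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class AnnotatorProfile:
    """Error-model parameters for one annotator group."""

    group: str
    sens: float
    spec: float
    p_detect: float = 1.0
    jitter_sd: float = 0.0
    scale_sd: float = 0.0
    fp_rate: float = 0.0
    fp_size: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        for name in ("sens", "spec", "p_detect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        for name in ("jitter_sd", "scale_sd", "fp_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class StudyBundle:
    """A complete synthetic study: corpus, split, crowd responses, provenance."""

    truths: list[ImageTruth]
    training_ids: tuple[str, ...]
    evaluation_ids: tuple[str, ...]
    records: list[AnnotationRecord]
    seed: int
    config: CorpusConfig
    profiles: tuple[AnnotatorProfile, ...]
    n_per_group: int


def default_profiles() -> list[AnnotatorProfile]:
    """Default per-group error profiles.

    The classification rates are calibrated so that pooling the three groups
    gives roughly 87% sensitivity / 71% specificity overall, with the trained
    nonmasters trading specificity for sensitivity (over-flagging after
    training) and masters in between.  Localization parameters are moderate
    noise: most expert lesions reproduced, ~6 px corner jitter, ~15% size
    noise, and under one spurious rectangle per annotated image.
    """
    return [
        AnnotatorProfile(
            group="nonmasters", sens=0.86, spec=0.77,
            p_detect=0.72, jitter_sd=6.0, scale_sd=0.15, fp_rate=0.6,
        ),
        AnnotatorProfile(
            group="masters", sens=0.84, spec=0.75,
            p_detect=0.70, jitter_sd=6.0, scale_sd=0.15, fp_rate=0.5,
        ),
        AnnotatorProfile(
            group="nonmasters_trained", sens=0.91, spec=0.60,
            p_detect=0.80, jitter_sd=5.0, scale_sd=0.12, fp_rate=0.8,
        ),
    ]


def _random_rectangle(rng: np.random.Generator, width: int, height: int,
                      size_range: tuple[int, int]) -> Rectangle:
    lo, hi = size_range
    w = int(rng.integers(lo, min(hi, width) + 1))
    h = int(rng.integers(lo, min(hi, height) + 1))
    x0 = int(rng.integers(0, width - w + 1))
    y0 = int(rng.integers(0, height - h + 1))
    return Rectangle(x0, y0, x0 + w, y0 + h)


def generate_corpus(
    config: CorpusConfig, seed: int
) -> tuple[list[ImageTruth], tuple[str, ...], tuple[str, ...]]:
    """Generate the ground-truth corpus and the training/evaluation split.

    Abnormal images carry 1-k lesion rectangles placed uniformly at random,
    with severe-class lesions drawn larger and more numerous than mild-class
    ones; normal images carry none.  Deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_CORPUS_KEY,)))
    truths: list[ImageTruth] = []
    classes = (
        [("severe", config.severe_lesion_count, config.severe_lesion_size)] * config.n_severe
        + [("mild", config.mild_lesion_count, config.mild_lesion_size)] * config.n_mild
        + [("normal", None, None)] * config.n_normal
    )
    for i, (label, count_range, size_range) in enumerate(classes):
        rects: tuple[Rectangle, ...] = ()
        if label != "normal":
            k = int(rng.integers(count_range[0], count_range[1] + 1))
            rects = tuple(
                _random_rectangle(rng, config.width, config.height, size_range)
                for _ in range(k)
            )
        truths.append(
            ImageTruth(
                image_id=f"img_{i:03d}",
                width=config.width,
                height=config.height,
                true_label=label,
                expert_rectangles=rects,
            )
        )
    normal_ids = [t.image_id for t in truths if t.true_label == "normal"]
    abnormal_ids = [t.image_id for t in truths if t.true_label != "normal"]
    train_normal = rng.choice(normal_ids, size=config.n_training_normal, replace=False)
    n_train_abnormal = config.n_training - config.n_training_normal
    train_abnormal = rng.choice(abnormal_ids, size=n_train_abnormal, replace=False)
    training_ids = tuple(sorted(str(i) for i in (*train_normal, *train_abnormal)))
    evaluation_ids = tuple(
        sorted(t.image_id for t in truths if t.image_id not in set(training_ids))
    )
    return truths, training_ids, evaluation_ids


def _perturb_rectangle(
    rect: Rectangle, rng: np.random.Generator, jitter_sd: float, scale_sd: float,
    width: int, height: int,
) -> Rectangle:
    """Scale about the center by exp(N(0, scale_sd^2)), jitter corners by
    N(0, jitter_sd^2), then round, re-order and clip."""
    s = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd > 0 else 1.0
    cx = (rect.x0 + rect.x1) / 2.0
    cy = (rect.y0 + rect.y1) / 2.0
    hw = rect.width * s / 2.0
    hh = rect.height * s / 2.0
    coords = np.array([cx - hw, cy - hh, cx + hw, cy + hh])
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, size=4)
    x0, y0, x1, y1 = np.rint(coords).astype(int)
    x0, x1 = min(x0, x1), max(x0, x1)
    y0, y1 = min(y0, y1), max(y0, y1)
    return Rectangle(x0, y0, x1, y1).clipped(width, height)


def simulate_crowd(
    truths: list[ImageTruth],
    evaluation_ids,
    profiles: list[AnnotatorProfile],
    n_per_group: int,
    seed: int,
    dropout: float = 0.0,
) -> list[AnnotationRecord]:
    """Simulate crowd responses on the evaluation images.

    Complete design by default: every simulated annotator responds to every
    evaluation image.  The label is Bernoulli from the profile's sens/spec
    given the true class; when the drawn label is nonhealthy and the image is
    abnormal, each expert rectangle is independently included with
    ``p_detect`` and perturbed; ``Poisson(fp_rate)`` spurious rectangles are
    added uniformly to any nonhealthy-labeled response.  With ``dropout > 0``
    an annotator abandons the task early with that probability, completing
    only a random prefix of the image sequence (an incomplete submission).
    Deterministic given ``seed``; annotators draw from independent substreams.
    """
    if not profiles:
        raise ValidationError("at least one annotator profile is required")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if not 0.0 <= dropout < 1.0:
        raise ValidationError("dropout must be in [0, 1)")
    truth_by_id = {t.image_id: t for t in truths}
    eval_ids = sorted(evaluation_ids)
    records: list[AnnotationRecord] = []
    for gi, profile in enumerate(profiles):
        for j in range(n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(_CROWD_KEY, gi, j))
            )
            n_images = len(eval_ids)
            if dropout > 0 and rng.random() < dropout and n_images > 1:
                n_images = int(rng.integers(1, len(eval_ids)))
            annotator_id = f"{profile.group}_{j:03d}"
            for image_id in eval_ids[:n_images]:
                truth = truth_by_id[image_id]
                if truth.is_healthy:
                    says_nonhealthy = rng.random() >= profile.spec
                else:
                    says_nonhealthy = rng.random() < profile.sens
                rects: list[Rectangle] = []
                if says_nonhealthy:
                    if not truth.is_healthy:
                        for rect in truth.expert_rectangles:
                            if rng.random() < profile.p_detect:
                                rects.append(
                                    _perturb_rectangle(
                                        rect, rng, profile.jitter_sd, profile.scale_sd,
                                        truth.width, truth.height,
                                    )
                                )
                    for _ in range(int(rng.poisson(profile.fp_rate))):
                        rects.append(
                            _random_rectangle(rng, truth.width, truth.height, profile.fp_size)
                        )
                records.append(
                    AnnotationRecord(
                        image_id=image_id,
                        annotator_id=annotator_id,
                        group=profile.group,
                        label="nonhealthy" if says_nonhealthy else "healthy",
                        rectangles=tuple(rects),
                    )
                )
    return records


def generate_study(
    config: CorpusConfig | None = None,
    profiles: list[AnnotatorProfile] | None = None,
    n_per_group: int = 20,
    seed: int = 0,
    dropout: float = 0.0,
) -> StudyBundle:
    """Generate corpus + crowd in one call (the default study design)."""
    config = config if config is not None else CorpusConfig()
    profiles = profiles if profiles is not None else default_profiles()
    truths, training_ids, evaluation_ids = generate_corpus(config, seed)
    records = simulate_crowd(truths, evaluation_ids, profiles, n_per_group, seed, dropout)
    return StudyBundle(
        truths=truths,
        training_ids=training_ids,
        evaluation_ids=evaluation_ids,
        records=records,
        seed=seed,
        config=config,
        profiles=tuple(profiles),
        n_per_group=n_per_group,
    )
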