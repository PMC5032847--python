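"""Crowd consensus masks and Dice agreement against the expert reference.

The annotation-accuracy arm of the analysis: for each abnormal image, every
annotator's rectangles are rasterized to a binary mask, the masks are averaged
into a per-pixel vote-fraction grid, the grid is thresholded at a consensus
vote fraction t, and the resulting fused mask is compared with the expert mask
by the Dice coefficient D = 2|A∩B| / (|A|+|B|).  Sweeping t produces the
Dice-versus-vote-threshold curve whose maximizing t is the operating consensus
threshold.

Conventions:

* thresholding uses >= , so a pixel marked by exactly a fraction t of the
  annotators is positive at threshold t (with 20 annotators, 5/20 votes meets
  t = 0.25);
* annotators who labeled an abnormal image healthy contribute an empty mask —
  the average runs over all of that image's annotators (configurable);
* Dice of two empty masks is undefined and returned as NaN; NaN values are
  excluded from medians.  Images with normal ground truth are excluded before
  the curve is computed, since no annotation is appropriate there.
* the curve reports the median over images with a seeded percentile-bootstrap
  confidence interval (resampling images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_data import (
    AnnotationRecord,
    AverageMask,
    BinaryMask,
    ImageTruth,
    ValidationError,
    annotator_mask,
    expert_mask,
)

# tolerance used when comparing vote counts against t * n, so that grid
# thresholds expressed in decimal (0.15, 0.25, ...) behave exactly at k/n
_VOTE_EPS = 1e-9

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass(frozen=True)
class ConsensusConfig:
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    bootstrap_reps: int = 2000
    bootstrap_seed: int = 0
    ci_level: float = 0.95
    include_healthy_labelers: bool = True

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.threshold_grid)
        object.__setattr__(self, "threshold_grid", grid)
        if not grid or any(not 0.0 < t <= 1.0 for t in grid):
            raise ValidationError("threshold grid values must lie in (0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("threshold grid must be strictly increasing")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")


@dataclass
class DiceCurve:
    """Median Dice per consensus threshold, with bootstrap CI and per-image values."""

    thresholds: np.ndarray          # (T,)
    median: np.ndarray              # (T,)
    ci_low: np.ndarray              # (T,)
    ci_high: np.ndarray             # (T,)
    per_image: np.ndarray           # (T, n_images), NaN where undefined
    image_ids: tuple[str, ...]
    n_images: int


def average_mask(masks: list[BinaryMask]) -> AverageMask:
    """Per-pixel fraction of masks positive at each pixel."""
    if not masks:
        raise ValidationError("average_mask needs at least one mask")
    shape = masks[0].pixels.shape
    if any(m.pixels.shape != shape for m in masks):
        raise ValidationError("masks have mismatched dimensions")
    counts = np.zeros(shape, dtype=np.int64)
    for m in masks:
        counts += m.pixels
    return AverageMask(counts=counts, n_annotators=len(masks))


def threshold_mask(avg: AverageMask, t: float) -> BinaryMask:
    """Pixel positive iff its vote fraction is >= t, for t in (0, 1]."""
    if not 0.0 < t <= 1.0:
        raise ValidationError(f"threshold must be in (0, 1], got {t}")
    return BinaryMask(avg.counts >= t * avg.n_annotators - _VOTE_EPS)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); NaN when both masks are empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValidationError("dice: mask dimensions differ")
    na, nb = a.positive_count, b.positive_count
    if na + nb == 0:
        return float("nan")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |A∩B|/|A∪B|, for sensitivity analysis; NaN when both empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValidationError("jaccard: mask dimensions differ")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    union = int(np.logical_or(a.pixels, b.pixels).sum())
    if union == 0:
        return float("nan")
    return inter / union


def _bootstrap_median_ci(
    values: np.ndarray, reps: int, seed: int, ci_level: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap of the per-threshold NaN-median, resampling images.

    ``values`` has shape (T, n_images); images are resampled jointly across
    thresholds so the curve's CIs share one resampling scheme.
    """
    n = values.shape[1]
    med = np.nanmedian(values, axis=1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boot = np.nanmedian(values[:, idx], axis=2)  # (T, reps)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.nanpercentile(boot, 100 * alpha, axis=1)
    hi = np.nanpercentile(boot, 100 * (1 - alpha), axis=1)
    return med, lo, hi


def image_vote_counts(
    records: list[AnnotationRecord], truth: ImageTruth,
    include_healthy_labelers: bool = True,
) -> AverageMask | None:
    """Vote-count grid for one image from its annotators' rectangle masks.

    Healthy-labeling annotators contribute an all-negative mask when
    ``include_healthy_labelers`` (they are in the denominator); otherwise they
    are dropped.  Returns None when no annotator remains.
    """
    counts = np.zeros((truth.height, truth.width), dtype=np.int64)
    n = 0
    for rec in records:
        if not include_healthy_labelers and rec.label == "healthy":
            continue
        counts += annotator_mask(rec, truth).pixels
        n += 1
    if n == 0:
        return None
    return AverageMask(counts=counts, n_annotators=n)


def dice_curve(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
    config: ConsensusConfig | None = None,
) -> DiceCurve:
    """Dice-vs-consensus-threshold curve over the abnormal evaluation images.

    Normal-truth images are excluded first.  For each remaining image the
    crowd average mask is thresholded at every grid value and compared with
    the expert mask by Dice; the curve reports the median across images with
    a seeded percentile-bootstrap CI.
    """
    config = config if config is not None else ConsensusConfig()
    thresholds = np.asarray(config.threshold_grid, dtype=float)
    by_image: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        if group is not None and rec.group != group:
            continue
        by_image.setdefault(rec.image_id, []).append(rec)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    for truth in truths:
        if truth.is_healthy:
            continue
        recs = by_image.get(truth.image_id)
        if not recs:
            continue
        avg = image_vote_counts(recs, truth, config.include_healthy_labelers)
        if avg is None:
            continue
        ref = expert_mask(truth)
        per_t = np.array([dice(threshold_mask(avg, t), ref) for t in thresholds])
        rows.append(per_t)
        ids.append(truth.image_id)
    if not rows:
        raise ValidationError("no abnormal image with annotations after filtering")

    per_image = np.stack(rows, axis=1)  # (T, n_images)
    med, lo, hi = _bootstrap_median_ci(
        per_image, config.bootstrap_reps, config.bootstrap_seed, config.ci_level
    )
    return DiceCurve(
        thresholds=thresholds,
        median=med,
        ci_low=lo,
        ci_high=hi,
        per_image=per_image,
        image_ids=tuple(ids),
        n_images=len(ids),
    )


def optimal_threshold(curve: DiceCurve) -> float:
    """Grid threshold maximizing the median Dice; ties break to the smallest t."""
    if curve.thresholds.size == 0:
        raise ValidationError("empty curve")
    return float(curve.thresholds[int(np.nanargmax(curve.median))])
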