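"""Classification-arm metrics and the area-correlation analysis.

Ground truth is dichotomized healthy (normal) versus nonhealthy (mild or
severe).  The metrics mirror a crowd-grading study design:

* pooled per-response sensitivity/specificity — each individual crowd response
  counts once, with Wilson score confidence intervals;
* majority-vote accuracy — fraction of images whose strict-majority (> 50%)
  crowd label matches ground truth (an exact tie counts as incorrect);
* ROC/AUC — the continuous score for an image is its nonhealthy vote fraction
  (share of responses labeling it nonhealthy); the empirical ROC sweeps all
  distinct scores, AUC is the trapezoidal area (equal to the pairwise
  concordance probability with ties counted 1/2), and its CI is a seeded
  percentile bootstrap resampling images;
* area correlation — across abnormal images, Pearson (and Spearman)
  correlation between the expert lesion area and the thresholded consensus
  mask area, in raw positive-pixel counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .annotation_data import AnnotationRecord, ImageTruth, ValidationError, expert_mask
from .consensus import image_vote_counts, threshold_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricResult:
    """A named point estimate with a 95% CI and the count it summarizes."""

    name: str
    group: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class RocResult:
    group: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_images: int


def _filter_records(records: list[AnnotationRecord], group: str | None):
    if group is None:
        return list(records)
    return [r for r in records if r.group == group]


def _truth_by_id(truths: list[ImageTruth]) -> dict[str, ImageTruth]:
    return {t.image_id: t for t in truths}


def pooled_sens_spec(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
    ci_level: float = 0.95,
) -> tuple[MetricResult, MetricResult]:
    """Pooled per-response sensitivity and specificity with Wilson score CIs.

    Sensitivity pools every response to a nonhealthy-truth image; specificity
    every response to a healthy-truth image.  Raises if either truth class
    received no responses.
    """
    recs = _filter_records(records, group)
    tmap = _truth_by_id(truths)
    counts = {"nonhealthy": [0, 0], "healthy": [0, 0]}  # class -> [correct, total]
    for rec in recs:
        truth = tmap.get(rec.image_id)
        if truth is None:
            raise ValidationError(f"no ground truth for image {rec.image_id!r}")
        cls = "healthy" if truth.is_healthy else "nonhealthy"
        counts[cls][1] += 1
        if rec.label == cls:
            counts[cls][0] += 1
    for cls, (_, total) in counts.items():
        if total == 0:
            raise ValidationError(f"no responses to {cls}-truth images")
    out = []
    for name, cls in (("sensitivity", "nonhealthy"), ("specificity", "healthy")):
        k, n = counts[cls]
        lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
        out.append(
            MetricResult(
                name=name, group=group if group is not None else "all",
                estimate=k / n, ci_low=float(lo), ci_high=float(hi), n=n,
            )
        )
    return out[0], out[1]


def majority_correct_fraction(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
) -> dict[str, float]:
    """Fraction of healthy and nonhealthy images with a correct strict majority.

    An image's majority label is the one held by strictly more than half of its
    responses; an exact tie means no majority and counts as incorrect.
    """
    recs = _filter_records(records, group)
    tmap = _truth_by_id(truths)
    votes: dict[str, list[str]] = {}
    for rec in recs:
        votes.setdefault(rec.image_id, []).append(rec.label)
    correct = {"healthy": [0, 0], "nonhealthy": [0, 0]}  # class -> [correct, images]
    for image_id, labels in votes.items():
        truth = tmap.get(image_id)
        if truth is None:
            raise ValidationError(f"no ground truth for image {image_id!r}")
        cls = "healthy" if truth.is_healthy else "nonhealthy"
        n_correct_label = sum(1 for lab in labels if lab == cls)
        correct[cls][1] += 1
        if n_correct_label * 2 > len(labels):
            correct[cls][0] += 1
    for cls, (_, n) in correct.items():
        if n == 0:
            raise ValidationError(f"no {cls}-truth image with responses")
    return {cls: k / n for cls, (k, n) in correct.items()}


def vote_fraction_scores(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
) -> pd.DataFrame:
    """Per-image nonhealthy vote fraction and dichotomized truth.

    Returns a DataFrame with columns ``image_id, score, is_nonhealthy, n_responses``;
    evaluation images with zero responses in the group are excluded with a
    logged warning.
    """
    recs = _filter_records(records, group)
    tmap = _truth_by_id(truths)
    tally: dict[str, list[int]] = {}
    for rec in recs:
        k_n = tally.setdefault(rec.image_id, [0, 0])
        k_n[1] += 1
        if rec.label == "nonhealthy":
            k_n[0] += 1
    responded = set(tally)
    skipped = [
        t.image_id for t in truths if t.image_id not in responded
    ]
    if skipped:
        logger.warning(
            "excluding %d image(s) with zero responses in group %s",
            len(skipped), group if group is not None else "all",
        )
    rows = []
    for t in truths:
        if t.image_id not in tally:
            continue
        k, n = tally[t.image_id]
        rows.append(
            {
                "image_id": t.image_id,
                "score": k / n,
                "is_nonhealthy": not t.is_healthy,
                "n_responses": n,
            }
        )
    return pd.DataFrame(rows, columns=["image_id", "score", "is_nonhealthy", "n_responses"])


def roc_auc(
    scores: pd.DataFrame,
    group: str = "all",
    bootstrap_reps: int = 2000,
    bootstrap_seed: int = 0,
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical ROC and trapezoidal AUC from per-image vote-fraction scores.

    AUC equals the probability that a random nonhealthy image outscores a
    random healthy one, ties counted 1/2.  The CI is a percentile bootstrap
    resampling images; degenerate one-class resamples are dropped.
    """
    y = scores["is_nonhealthy"].to_numpy(dtype=bool)
    s = scores["score"].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValidationError("ROC needs both truth classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(bootstrap_seed)
    n = len(y)
    boot = []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        boot.append(roc_auc_score(yb, s[idx]))
    alpha = (1 - ci_level) / 2
    if boot:
        lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    else:  # pragma: no cover - tiny degenerate inputs
        lo = hi = auc
    return RocResult(
        group=group, fpr=fpr, tpr=tpr, auc=auc,
        ci_low=float(lo), ci_high=float(hi), n_images=n,
    )


def per_response_operating_point(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
) -> tuple[float, float]:
    """Single ROC operating point from the pooled per-response rates.

    The sensitivity-analysis alternative to the vote-fraction ROC: treating
    each binary response as its own prediction yields one (FPR, TPR) point,
    (1 - specificity, sensitivity).
    """
    sens, spec = pooled_sens_spec(records, truths, group)
    return 1.0 - spec.estimate, sens.estimate


def area_correlation(
    records: list[AnnotationRecord],
    truths: list[ImageTruth],
    group: str | None = None,
    threshold: float = 0.25,
    include_healthy_labelers: bool = True,
    log_area: bool = False,
) -> tuple[pd.DataFrame, float, float]:
    """Expert-vs-consensus lesion area correlation across abnormal images.

    For each nonhealthy image, pairs the expert mask's positive-pixel count
    with the positive-pixel count of the consensus mask thresholded at
    ``threshold``.  Returns (pairs, Pearson r, Spearman rho); the coefficients
    are NaN when fewer than 3 images are available or either margin has zero
    variance.  ``log_area`` applies log1p to both counts before correlating.
    """
    recs = _filter_records(records, group)
    by_image: dict[str, list[AnnotationRecord]] = {}
    for rec in recs:
        by_image.setdefault(rec.image_id, []).append(rec)
    rows = []
    for truth in truths:
        if truth.is_healthy:
            continue
        image_recs = by_image.get(truth.image_id)
        if not image_recs:
            continue
        avg = image_vote_counts(image_recs, truth, include_healthy_labelers)
        if avg is None:
            continue
        crowd_area = threshold_mask(avg, threshold).positive_count
        rows.append(
            {
                "image_id": truth.image_id,
                "expert_area": expert_mask(truth).positive_count,
                "crowd_area": crowd_area,
            }
        )
    pairs = pd.DataFrame(rows, columns=["image_id", "expert_area", "crowd_area"])
    x = pairs["expert_area"].to_numpy(dtype=float)
    y = pairs["crowd_area"].to_numpy(dtype=float)
    if log_area:
        x, y = np.log1p(x), np.log1p(y)
    if len(pairs) < 3 or np.std(x) == 0 or np.std(y) == 0:
        logger.warning("area correlation undefined (<3 points or zero variance)")
        return pairs, float("nan"), float("nan")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pairs, pearson, spearman
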