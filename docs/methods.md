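# Methods

## Data model and coordinate conventions

Annotations are rectangles in 0-based pixel coordinates, x rightwards and
y downwards, half-open on both axes (`[x0, x1) × [y0, y1)`), so the pixel area
is exactly `(x1−x0)(y1−y0)`. Click-drag input plausibly overshoots the image,
so rectangles are clipped to the image bounds on ingest rather than rejected;
zero-area rectangles are kept and flagged degenerate (they rasterize to an
empty mask). A response whose class label is "healthy" may still carry
rectangles; the classification arm ignores them and the annotation arm treats
the record like any other. Files are tab-separated text with one response (or
one ground-truth image) per row and rectangles serialized as
semicolon-separated `x0,y0,x1,y1` quadruples; masks export to single-channel
PNG (0/255).

## Consensus masks and the Dice curve

For one image, each annotator's mask is the pixelwise union of their
rectangles (empty for a healthy label). The average mask stores integer vote
counts, so every vote fraction is an exact k/n. Thresholding uses **≥**: a
pixel marked by exactly a fraction t of annotators is positive at threshold t
(with 20 annotators, 5/20 votes meets t = 0.25). Annotators who labeled an
abnormal image healthy stay in the denominator by default
(`include_healthy_labelers=True`) — the average is taken across all of the
image's annotators — with a switch to drop them for sensitivity analysis.

Agreement is the Dice coefficient D = 2|A∩B|/(|A|+|B|). D of two empty masks
is undefined and propagated as NaN (excluded from medians); an all-empty crowd
mask on an abnormal image gives D = 0, since the expert mask is non-empty.
Some texts verbally describe Dice as "intersection over union", which is the
Jaccard index J = |A∩B|/|A∪B|; this package implements the standard Dice
formula under the name `dice` (consistent with the 0/1 range semantics and the
>0.6 "substantial agreement" convention) and provides `jaccard` alongside
(J = D/(2−D), monotone in D, so the optimal threshold is unchanged).

Normal-truth images are excluded before the curve is computed — no annotation
is appropriate there, so with the default corpus 60 of the 84 evaluation
images enter. The curve reports the median Dice across images per grid
threshold (default grid 0.05…0.95 in steps of 0.05, which contains the
conventionally reported 0.15/0.20/0.25) with a percentile-bootstrap 95 % CI
(default 2000 replicates, resampling images, seeded). The optimal threshold is
the grid value maximizing the median; ties break toward the smallest
threshold (the cheapest consensus achieving the maximum).

## Classification metrics

Sensitivity and specificity are pooled *per response*: every individual
response to a nonhealthy-truth (resp. healthy-truth) image counts once.
Proportion CIs use the Wilson score interval, which behaves well near the
boundary; bootstrap percentile intervals are used for AUC and the Dice
medians. Majority-vote accuracy requires a strict majority (>50 %); an exact
tie is no majority and counts as incorrect. No multiple-testing correction is
applied; every interval is marginal.

The ROC score for an image is its nonhealthy vote fraction. This is the
package's explicit construction: individual responses are binary, so some
continuous per-image score is needed to trace a full curve, and the vote
fraction is the natural crowd statistic (it is also what the majority vote
thresholds at 0.5). The empirical ROC sweeps all distinct scores; AUC is the
trapezoidal area, identical to the Mann–Whitney concordance probability with
ties counted ½ (the test suite checks this equivalence against a brute-force
pairwise oracle). Computation is delegated to scikit-learn's
`roc_curve`/`roc_auc_score`; the oracle in the tests is independent of that
path.

The area correlation pairs, per abnormal image, the expert mask's
positive-pixel count with the thresholded consensus mask's count (threshold =
the Dice-optimal one by default), and reports Pearson and Spearman
coefficients on raw counts (a `log_area` option applies log1p first, default
off). Fewer than 3 images or zero variance in either margin makes the
coefficient undefined; it is reported as NaN with a warning rather than
raised.

## The synthetic study generator

The generator emulates the structure of a crowdsourced retinal-grading study:
100 images — 10 severely abnormal, 60 mildly abnormal, 30 normal — with 16
training images (6 normal, 10 abnormal) held out, leaving 84 evaluation
images of which 24 are normal. The training split is drawn at random within
those class quotas. Lesions are axis-aligned rectangles placed uniformly:
mild images carry 1–3 lesions of side 20–60 px, severe images 3–6 lesions of
side 40–120 px on a 512×512 grid, so severe pathology is larger and more
numerous. Rectangular lesions keep the expert reference and the annotator
input in the same geometry; irregular lesion shapes are out of scope.

Annotators are sampled from per-group error profiles:

| parameter | meaning | units | defaults (nonmasters / masters / trained) |
|---|---|---|---|
| `sens` | P(label nonhealthy \| abnormal image) | probability | 0.86 / 0.84 / 0.91 |
| `spec` | P(label healthy \| normal image) | probability | 0.77 / 0.75 / 0.60 |
| `p_detect` | per-lesion probability of reproducing an expert rectangle | probability | 0.72 / 0.70 / 0.80 |
| `jitter_sd` | Gaussian s.d. added to rectangle corners | px | 6 / 6 / 5 |
| `scale_sd` | s.d. of log-normal size noise (about the center) | log scale | 0.15 / 0.15 / 0.12 |
| `fp_rate` | expected spurious rectangles per nonhealthy-labeled image (Poisson) | count | 0.6 / 0.5 / 0.8 |

The classification defaults are calibrated so the three groups pool to ≈87 %
sensitivity and ≈71 % specificity overall, with the compulsory-training group
trading specificity for sensitivity (over-flagging after training: its low
specificity also reproduces a majority-vote accuracy on normal images well
below the other groups') and masters close to untrained nonmasters. The
localization defaults are moderate noise chosen to make consensus fusion
meaningfully better than a single annotator without overwhelming the signal —
roughly three-quarters of lesions reproduced, corner noise small relative to
lesion size, and under one spurious rectangle per annotated response.
Spurious rectangles default to mild-lesion size (20–60 px).

Responses form a complete design (every annotator grades every evaluation
image). Real studies see incomplete submissions; a `dropout` probability
(default 0) makes an annotator abandon the task after a random prefix of
images, but no behavioral dropout mechanism is modeled. All randomness flows
from one master seed through `numpy.random.SeedSequence` spawn keys — the
corpus and every annotator use independent substreams — so adding annotators
or groups never perturbs existing responses, and identical (config, seed) is
bit-identical.

**What passing tests do and do not show.** The simulator has homogeneous
annotators within a group, no per-image difficulty, independent responses, and
rectangular lesions. Under these idealizations the pooled rates converge to
the profile parameters (verified within 3 binomial standard errors at the
default size) and the vote-fraction AUC saturates near 1 with 20+ annotators
per image — real crowds, with correlated errors and genuinely ambiguous
images, yield lower AUCs and Dice medians. Tests on the simulator validate
the *analysis machinery* (estimators recover known generating parameters;
limits, monotonicities and oracle equivalences hold), not the field accuracy
of crowdsourcing.

## Numerical choices and degenerate inputs

- Vote thresholding compares integer counts against `t·n` with a 1e-9
  tolerance so decimal grid thresholds behave exactly at k/n.
- Bootstrap CIs are percentile intervals with a fixed, configurable seed;
  bootstrap replicates of the AUC that lose one class are dropped.
- `optimal_threshold` uses first-maximum tie-breaking (smallest threshold).
- Degenerate inputs raise a `ValidationError` naming the offending row or
  input (inverted rectangles, unknown labels, duplicate responses, one-class
  ROC input, empty mask lists, mismatched dimensions); undefined statistics
  (Dice of two empty masks, correlation on <3 points or zero variance) are
  NaN, logged, and excluded from summaries rather than raised.

## Problem sizes in the test suite

Unit and property tests run on toy grids (≤64×64) where brute-force per-pixel
and pairwise oracles are exact; pipeline-level tests use a reduced corpus
(12 images, 64×64) with trimmed bootstrap replicates; calibration and
recovery tests use the full default study (100 images, 512×512, 3×20
annotators), which generates and analyzes in a few seconds. The acceptance
script runs the default study end to end.

## Known limitations

- No probabilistic label-fusion estimators (STAPLE, Dawid–Skene) — simple
  averaging and thresholding only, by design.
- No modeling of training-induced bias beyond the static profile differences,
  and no monetary-incentive or dropout behavior.
- The ROC construction from binary responses is a choice;
  `per_response_operating_point` gives the single-point alternative (one
  (FPR, TPR) pair from the pooled rates) for sensitivity analysis.
- Confidence intervals are marginal; no DeLong AUC variance.
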