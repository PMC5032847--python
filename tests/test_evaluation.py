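"""Classification metrics: pooled rates with Wilson CIs, majority vote,
vote-fraction ROC/AUC against a concordance oracle, and area correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdgrade import (
    AnnotationRecord,
    AnnotatorProfile,
    ImageTruth,
    Rectangle,
    ValidationError,
    area_correlation,
    generate_study,
    majority_correct_fraction,
    pooled_sens_spec,
    roc_auc,
    vote_fraction_scores,
)
from conftest import noise_free_profiles


def auc_bruteforce(scores, truths) -> float:
    """Pairwise concordance probability with ties counted 1/2: the oracle."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def make_records(labels_by_image, group="masters"):
    """labels_by_image: {image_id: [label, ...]} -> records with unique annotators."""
    records = []
    for image_id, labels in labels_by_image.items():
        for i, label in enumerate(labels):
            records.append(AnnotationRecord(image_id, f"a{i}", group, label))
    return records


H = ImageTruth("h1", 8, 8, "normal")
H2 = ImageTruth("h2", 8, 8, "normal")
NH = ImageTruth("n1", 8, 8, "mild", (Rectangle(0, 0, 4, 4),))
NH2 = ImageTruth("n2", 8, 8, "mild", (Rectangle(2, 2, 6, 6),))


class TestPooledSensSpec:
    def test_all_correct_gives_one(self):
        records = make_records({"h1": ["healthy"] * 3, "n1": ["nonhealthy"] * 3})
        sens, spec = pooled_sens_spec(records, [H, NH])
        assert sens.estimate == 1.0 and spec.estimate == 1.0

    def test_ratio_by_construction(self):
        labels = ["nonhealthy"] * 87 + ["healthy"] * 13
        records = [AnnotationRecord("n1", f"a{i}", "masters", lab)
                   for i, lab in enumerate(labels)]
        records += make_records({"h1": ["healthy"] * 10})
        sens, _ = pooled_sens_spec(records, [H, NH])
        assert sens.estimate == pytest.approx(0.87)
        assert sens.n == 100

    def test_wilson_interval_matches_closed_form(self):
        # hand-evaluated Wilson formula for 87 successes of 100 at z = 1.95996...
        labels = ["nonhealthy"] * 87 + ["healthy"] * 13
        records = [AnnotationRecord("n1", f"a{i}", "masters", lab)
                   for i, lab in enumerate(labels)]
        records += make_records({"h1": ["healthy"] * 10})
        sens, _ = pooled_sens_spec(records, [H, NH])
        z = 1.959963984540054
        p, n = 0.87, 100
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert sens.ci_low == pytest.approx(center - half, abs=1e-12)
        assert sens.ci_high == pytest.approx(center + half, abs=1e-12)

    def test_missing_truth_class_rejected(self):
        records = make_records({"n1": ["nonhealthy"] * 3})
        with pytest.raises(ValidationError, match="healthy"):
            pooled_sens_spec(records, [H, NH])

    def test_group_counts_partition_total(self, default_bundle):
        total = pooled_sens_spec(default_bundle.records, default_bundle.truths)[0].n
        per_group = sum(
            pooled_sens_spec(default_bundle.records, default_bundle.truths, g)[0].n
            for g in ("nonmasters", "masters", "nonmasters_trained")
        )
        assert per_group == total

    def test_recovers_generating_rates(self, default_bundle):
        """Pooled estimates recover each profile's sens/spec within 3 binomial
        standard errors on the default study."""
        for profile in default_bundle.profiles:
            sens, spec = pooled_sens_spec(
                default_bundle.records, default_bundle.truths, profile.group
            )
            for metric, p in ((sens, profile.sens), (spec, profile.spec)):
                se = math.sqrt(p * (1 - p) / metric.n)
                assert abs(metric.estimate - p) < 3 * se


class TestMajorityVote:
    def test_majority_correct_everywhere(self):
        records = make_records({
            "h1": ["healthy", "healthy", "nonhealthy"],
            "n1": ["nonhealthy", "nonhealthy", "healthy"],
        })
        frac = majority_correct_fraction(records, [H, NH])
        assert frac == {"healthy": 1.0, "nonhealthy": 1.0}

    def test_exact_tie_counts_incorrect(self):
        records = make_records({
            "h1": ["healthy", "healthy", "nonhealthy", "nonhealthy"],
            "n1": ["nonhealthy"] * 4,
        })
        frac = majority_correct_fraction(records, [H, NH])
        assert frac["healthy"] == 0.0

    def test_fraction_over_images(self):
        by_image = {"n1": ["nonhealthy"] * 3}
        by_image.update({"h1": ["healthy"] * 3, "h2": ["nonhealthy"] * 3})
        records = make_records(by_image)
        frac = majority_correct_fraction(records, [H, H2, NH])
        assert frac["healthy"] == 0.5


class TestVoteFractionScores:
    def test_score_is_nonhealthy_fraction(self):
        records = make_records({"n1": ["nonhealthy"] * 13 + ["healthy"] * 7})
        scores = vote_fraction_scores(records, [NH])
        assert scores.loc[0, "score"] == pytest.approx(0.65)
        assert scores.loc[0, "n_responses"] == 20

    def test_zero_response_images_excluded_with_warning(self, caplog):
        records = make_records({"n1": ["nonhealthy"] * 3})
        with caplog.at_level("WARNING", logger="crowdgrade.evaluation"):
            scores = vote_fraction_scores(records, [H, NH])
        assert list(scores["image_id"]) == ["n1"]
        assert "zero responses" in caplog.text

    def test_noise_free_crowd_fully_separates(self, tiny_config):
        bundle = generate_study(tiny_config, noise_free_profiles(), 3, seed=2)
        scores = vote_fraction_scores(bundle.records, bundle.truths)
        assert set(scores.loc[scores.is_nonhealthy, "score"]) == {1.0}
        assert set(scores.loc[~scores.is_nonhealthy, "score"]) == {0.0}


class TestRocAuc:
    def _frame(self, scores, truths):
        return pd.DataFrame({
            "image_id": [f"im{i}" for i in range(len(scores))],
            "score": scores, "is_nonhealthy": truths,
            "n_responses": [1] * len(scores),
        })

    def test_perfect_separation(self):
        res = roc_auc(self._frame([0.9, 0.8, 0.1, 0.2], [True, True, False, False]),
                      bootstrap_reps=50)
        assert res.auc == 1.0

    def test_pure_ties_give_half(self):
        res = roc_auc(self._frame([0.5] * 6, [True, True, True, False, False, False]),
                      bootstrap_reps=50)
        assert res.auc == 0.5

    def test_tied_scores_counted_half(self):
        # frozen from the brute-force concordance oracle: (1+1+0.5+1+0.5+1)/6 = 5/6
        scores = [0.9, 0.6, 0.6, 0.6, 0.1]
        truths = [True, True, True, False, False]
        assert auc_bruteforce(scores, truths) == pytest.approx(5 / 6)
        res = roc_auc(self._frame(scores, truths), bootstrap_reps=50)
        assert res.auc == pytest.approx(5 / 6)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(self._frame([0.1, 0.9], [True, True]))

    def test_curve_anchored_and_monotone(self, default_bundle):
        scores = vote_fraction_scores(default_bundle.records, default_bundle.truths)
        res = roc_auc(scores, bootstrap_reps=100)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert res.ci_low <= res.auc <= res.ci_high

    @settings(max_examples=100, derandomize=True)
    @given(
        scores=st.lists(st.sampled_from([i / 10 for i in range(11)]),
                        min_size=2, max_size=30),
        data=st.data(),
    )
    def test_matches_concordance_oracle(self, scores, data):
        truths = data.draw(st.lists(st.booleans(), min_size=len(scores),
                                    max_size=len(scores)))
        if all(truths) or not any(truths):
            truths[0] = not truths[0]
        res = roc_auc(self._frame(scores, truths), bootstrap_reps=1)
        assert res.auc == pytest.approx(auc_bruteforce(scores, truths))

    def test_auc_increases_with_annotator_quality(self):
        """A ladder of generating profiles with increasing sens+spec yields
        increasing vote-fraction AUC (corpus sized so no rung saturates)."""
        from crowdgrade import CorpusConfig
        corpus = CorpusConfig(
            n_severe=3, n_mild=12, n_normal=10, n_training=0, n_training_normal=0,
            width=64, height=64, mild_lesion_size=(6, 14), severe_lesion_size=(10, 24),
        )
        aucs = []
        for sens, spec in [(0.55, 0.5), (0.7, 0.6), (0.85, 0.75)]:
            profile = AnnotatorProfile(group="masters", sens=sens, spec=spec)
            bundle = generate_study(corpus, [profile], 8, seed=6)
            scores = vote_fraction_scores(bundle.records, bundle.truths)
            aucs.append(roc_auc(scores, bootstrap_reps=1).auc)
        assert aucs[0] < aucs[1] < aucs[2]


def test_per_response_operating_point_matches_pooled_rates():
    from crowdgrade import per_response_operating_point
    records = make_records({"h1": ["healthy"] * 7 + ["nonhealthy"] * 3,
                            "n1": ["nonhealthy"] * 9 + ["healthy"] * 1})
    fpr, tpr = per_response_operating_point(records, [H, NH])
    assert fpr == pytest.approx(0.3)
    assert tpr == pytest.approx(0.9)


class TestAreaCorrelation:
    def test_perfect_consensus_gives_unit_correlation(self, tiny_config):
        bundle = generate_study(tiny_config, noise_free_profiles(), 4, seed=1)
        pairs, pearson, spearman = area_correlation(bundle.records, bundle.truths)
        assert np.array_equal(pairs["expert_area"], pairs["crowd_area"])
        assert pearson == pytest.approx(1.0)
        assert spearman == pytest.approx(1.0)

    def test_collinear_areas_give_unit_pearson(self):
        # expert areas 10, 20, 30 px; every annotator doubles the height,
        # so crowd areas are exactly 2x: Pearson r = 1 by collinearity
        truths, records = [], []
        for i, w in enumerate((5, 10, 15)):
            tid = f"im{i}"
            truths.append(ImageTruth(tid, 32, 32, "mild", (Rectangle(0, 0, w, 2),)))
            for a in range(3):
                records.append(AnnotationRecord(tid, f"a{a}", "masters", "nonhealthy",
                                                (Rectangle(0, 0, w, 4),)))
        pairs, pearson, _ = area_correlation(records, truths, threshold=0.25)
        assert list(pairs["expert_area"]) == [10, 20, 30]
        assert list(pairs["crowd_area"]) == [20, 40, 60]
        assert pearson == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        truths, records = [], []
        for i in range(3):
            tid = f"im{i}"
            truths.append(ImageTruth(tid, 16, 16, "mild", (Rectangle(0, 0, 4, 4),)))
            records.append(AnnotationRecord(tid, "a0", "masters", "nonhealthy",
                                            (Rectangle(0, 0, 4, 4),)))
        pairs, pearson, spearman = area_correlation(records, truths)
        assert len(pairs) == 3
        assert np.isnan(pearson) and np.isnan(spearman)

    def test_too_few_points_undefined(self):
        truths = [ImageTruth("im0", 16, 16, "mild", (Rectangle(0, 0, 4, 4),))]
        records = [AnnotationRecord("im0", "a0", "masters", "nonhealthy",
                                    (Rectangle(0, 0, 4, 4),))]
        _, pearson, _ = area_correlation(records, truths)
        assert np.isnan(pearson)
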