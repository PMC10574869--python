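"""Metric formulas vs. tally oracles, k-fold splits, threshold sweep."""

import numpy as np
import pytest

from flatfoot.diagnosis import MILD, MODERATE, NORMAL
from flatfoot.evaluation import (
    UNDEFINED,
    EvaluationError,
    class_metrics,
    confusion,
    kfold_split,
    macro_average,
    overall_accuracy,
    per_angle_error_rates,
    threshold_sweep,
)

CLASSES = (NORMAL, MILD, MODERATE)


def tally_oracle(pred, truth, cls):
    tp = sum(p == cls and t == cls for p, t in zip(pred, truth))
    fp = sum(p == cls and t != cls for p, t in zip(pred, truth))
    fn = sum(p != cls and t == cls for p, t in zip(pred, truth))
    tn = len(pred) - tp - fp - fn
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_predictions_have_no_errors(self):
        truth = [NORMAL, MILD, MODERATE, MILD]
        cs = confusion(truth, truth)
        for c in cs.classes:
            assert cs[c]["FP"] == 0 and cs[c]["FN"] == 0

    def test_constant_predictor_fp_counts_other_truths(self):
        truth = [NORMAL] * 4 + [MILD] * 3 + [MODERATE] * 2
        pred = [NORMAL] * 9
        cs = confusion(pred, truth, classes=CLASSES)
        assert cs[NORMAL]["FP"] == 5
        assert cs[MILD]["FN"] == 3

    def test_random_vectors_match_tally_oracle(self, rng):
        for _ in range(20):
            truth = rng.choice(CLASSES, size=60).tolist()
            pred = rng.choice(CLASSES, size=60).tolist()
            cs = confusion(pred, truth, classes=CLASSES)
            for c in CLASSES:
                tp, fp, fn, tn = tally_oracle(pred, truth, c)
                assert (cs[c]["TP"], cs[c]["FP"], cs[c]["FN"], cs[c]["TN"]) == (tp, fp, fn, tn)
                assert tp + fp + fn + tn == cs.n_total

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion([NORMAL], [NORMAL, MILD])


class TestClassMetrics:
    def test_direct_arithmetic_example(self):
        cs = confusion(
            [NORMAL] * 10 + [MILD] * 10,
            [NORMAL] * 9 + [MILD] + [MILD] * 10,
            classes=(NORMAL, MILD),
        )
        m = class_metrics(cs, NORMAL)  # TP=9 FP=1 FN=0 TN=10
        assert m["precision"] == pytest.approx(90.0)
        assert m["recall"] == pytest.approx(100.0)
        assert m["accuracy"] == pytest.approx(95.0)

    def test_f_score_is_fixed_point_when_precision_equals_recall(self, rng):
        for _ in range(100):
            truth = rng.choice(CLASSES, size=40).tolist()
            pred = list(truth)
            # introduce symmetric confusion so precision == recall for NORMAL
            cs = confusion(pred, truth, classes=CLASSES)
            m = class_metrics(cs, NORMAL)
            if m["precision"] is not UNDEFINED and m["precision"] == m["recall"]:
                assert m["f_score"] == pytest.approx(m["precision"])

    def test_accuracy_and_error_rate_are_complementary(self, rng):
        for _ in range(100):
            truth = rng.choice(CLASSES, size=30).tolist()
            pred = rng.choice(CLASSES, size=30).tolist()
            cs = confusion(pred, truth, classes=CLASSES)
            for c in CLASSES:
                m = class_metrics(cs, c)
                assert m["accuracy"] + m["error_rate"] == pytest.approx(100.0)

    def test_f_score_bounded_by_precision_and_recall(self, rng):
        for _ in range(100):
            truth = rng.choice(CLASSES, size=25).tolist()
            pred = rng.choice(CLASSES, size=25).tolist()
            m = class_metrics(confusion(pred, truth, classes=CLASSES), NORMAL)
            if UNDEFINED in (m["precision"], m["recall"], m["f_score"]):
                continue
            assert min(m["precision"], m["recall"]) - 1e-9 <= m["f_score"]
            assert m["f_score"] <= max(m["precision"], m["recall"]) + 1e-9

    def test_zero_denominator_yields_undefined_marker(self):
        cs = confusion([MILD, MILD], [MILD, MILD], classes=(NORMAL, MILD))
        m = class_metrics(cs, NORMAL)  # NORMAL never predicted nor true
        assert m["precision"] is UNDEFINED
        assert m["recall"] is UNDEFINED
        assert m["accuracy"] == pytest.approx(100.0)

    def test_macro_average_skips_undefined(self):
        mean, skipped = macro_average([50.0, UNDEFINED, 100.0])
        assert mean == pytest.approx(75.0)
        assert skipped == 1


class TestOverallAccuracy:
    def test_perfect_angles_give_100(self):
        truth = [NORMAL, MILD]
        preds = {a: list(truth) for a in ("CIA", "AA", "MA")}
        assert overall_accuracy(preds, truth) == pytest.approx(100.0)

    def test_mean_of_per_angle_accuracies(self, rng):
        truth = rng.choice(CLASSES, size=50).tolist()
        preds = {a: rng.choice(CLASSES, size=50).tolist() for a in ("CIA", "AA", "MA")}
        want = np.mean(
            [100.0 * np.mean([p == t for p, t in zip(preds[a], truth)]) for a in ("CIA", "AA", "MA")]
        )
        assert overall_accuracy(preds, truth) == pytest.approx(want)

    def test_missing_angle_list_rejected(self):
        with pytest.raises(EvaluationError, match="MA"):
            overall_accuracy({"CIA": [NORMAL], "AA": [NORMAL]}, [NORMAL])


class TestPerAngleErrorRates:
    def test_perfect_predictions_are_zero(self):
        truth = [NORMAL, MILD, MODERATE]
        preds = {a: list(truth) for a in ("CIA", "AA", "MA")}
        rates = per_angle_error_rates(preds, truth, MILD)
        assert all(v == 0.0 for v in rates.values())

    def test_one_bad_angle_matches_tally_oracle(self, rng):
        truth = rng.choice(CLASSES, size=40).tolist()
        good = list(truth)
        bad = [MODERATE if t == MILD else t for t in truth]  # always wrong on mild
        preds = {"CIA": good, "AA": bad, "MA": good}
        rates = per_angle_error_rates(preds, truth, MILD)
        tp, fp, fn, tn = tally_oracle(bad, truth, MILD)
        assert rates["AA"] == pytest.approx(100.0 * (fn + fp) / len(truth))
        assert rates["CIA"] == 0.0

    def test_rates_bounded(self, rng):
        truth = rng.choice(CLASSES, size=30).tolist()
        preds = {a: rng.choice(CLASSES, size=30).tolist() for a in ("CIA", "AA", "MA")}
        for c in CLASSES:
            for v in per_angle_error_rates(preds, truth, c).values():
                assert 0.0 <= v <= 100.0


class TestKFoldSplit:
    def test_hundred_items_ten_equal_folds(self):
        folds, pairs = kfold_split(100, k=10, seed=1)
        assert len(folds) == 10
        assert all(len(f) == 10 for f in folds)
        assert len(pairs) == 10

    def test_folds_partition_indices(self):
        folds, pairs = kfold_split(53, k=10, seed=2)
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(53))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, test in pairs:
            assert set(train) | set(test) == set(range(53))
            assert not set(train) & set(test)

    def test_seeded_determinism(self):
        a, _ = kfold_split(40, k=10, seed=7)
        b, _ = kfold_split(40, k=10, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_items_rejected(self):
        with pytest.raises(EvaluationError):
            kfold_split(5, k=10)


@pytest.fixture(scope="module")
def sweep_inputs():
    from flatfoot.phantom import sample_dataset, build_templates

    dataset, _ = sample_dataset({"normal": 1, "mild": 1, "moderate": 1}, seed=31)
    library = build_templates(dataset)
    return dataset, library


class TestThresholdSweep:

    def test_own_template_set_localizes_perfectly_at_every_threshold(self):
        # templates cropped from the evaluated image itself: the exact crop
        # start scores R = 0, so the rank-1 match is the true location up to
        # the sub-pixel rounding of the crop grid (d <= sqrt(2)/2)
        from flatfoot.phantom import sample_dataset, build_templates

        dataset, _ = sample_dataset({"normal": 1}, seed=32)
        library = build_templates(dataset)
        table = threshold_sweep(
            dataset, library, thresholds=(0.5, 0.7, 0.9), max_templates_per_poi=None
        )
        assert (table["n_localized"] == 9).all()
        assert (table["mean_localization_score"] >= 1 / (1 + np.sqrt(2))).all()

    def test_candidate_counts_monotone_and_manual_recount(self, sweep_inputs):
        dataset, library = sweep_inputs
        table = threshold_sweep(dataset, library, thresholds=(0.6, 0.75, 0.9), top_k=None)
        counts = table["n_candidates"].tolist()
        assert counts == sorted(counts, reverse=True)
        # manual recomputation on the first phantom, first PoI
        from flatfoot.template_matching import ImageMatcher

        img, _ = dataset[0]
        tmpl = library.templates_for(1, limit=1)[0]
        values = ImageMatcher(np.asarray(img.pixels, float)).score(tmpl).values
        manual = int(((1 - values) >= 0.9).sum())
        # that count is part of the 0.9 row's total
        assert manual <= table.loc[table.threshold == 0.9, "n_candidates"].item()

    def test_threshold_outside_unit_interval_rejected(self, sweep_inputs):
        dataset, library = sweep_inputs
        with pytest.raises(EvaluationError):
            threshold_sweep(dataset, library, thresholds=(0.5, 1.2))
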