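"""Metric panel and the balanced-resampling validation protocol."""

import numpy as np
import pytest
from scipy import stats

import molscreen as ms
from molscreen.evaluation import ConfusionCounts


def brute_force_auroc(scores, labels):
    """Independent oracle: pairwise concordance with ties counting 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


class TestConfusionCounts:
    @pytest.mark.parametrize("labels,preds,expected", [
        ([1, 1, 0, 0], [1, 0, 0, 1], (1, 1, 1, 1)),
        ([1, 1, 1, 0, 0], [1, 1, 0, 1, 0], (2, 1, 1, 1)),
    ])
    def test_examples(self, labels, preds, expected):
        c = ms.confusion_counts(labels, preds)
        assert (c.tp, c.fn, c.tn, c.fp) == expected

    def test_perfect_predictions(self):
        c = ms.confusion_counts([1, 0, 1, 0, 0], [1, 0, 1, 0, 0])
        assert c.fn == c.fp == 0 and c.tp + c.tn == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ms.confusion_counts([1, 0], [1])

    def test_matches_per_item_tally_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = ms.confusion_counts(y, p)
            tally = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
            for yi, pi in zip(y, p):
                tally[("tp" if pi else "fn") if yi else ("fp" if pi else "tn")] += 1
            assert (c.tp, c.fn, c.tn, c.fp) == (
                tally["tp"], tally["fn"], tally["tn"], tally["fp"])
            assert c.total == n


class TestMetricsFromCounts:
    def test_formula_evaluation(self):
        m = ms.metrics_from_counts(ConfusionCounts(tp=3, fn=2, tn=4, fp=1))
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.60)
        assert m.accuracy == pytest.approx(0.70)
        assert m.specificity == pytest.approx(0.80)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        m = ms.metrics_from_counts(ConfusionCounts(10, 0, 10, 0))
        assert (m.accuracy, m.precision, m.sensitivity, m.specificity, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_fractional_averaged_counts(self):
        m = ms.metrics_from_counts(ConfusionCounts(tp=134, fn=20, tn=11.6, fp=8.3))
        assert m.precision == pytest.approx(134 / 142.3)
        assert m.sensitivity == pytest.approx(134 / 154)
        assert m.specificity == pytest.approx(11.6 / 19.9)

    def test_zero_denominators_flagged_not_raised(self):
        m = ms.metrics_from_counts(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert m.precision is None and m.sensitivity is None
        assert "precision" in m.undefined and "sensitivity" in m.undefined
        assert m.accuracy == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ms.metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(25):
            c = ConfusionCounts(*rng.integers(1, 50, 4))
            m = ms.metrics_from_counts(c)
            assert m.f1 == pytest.approx(
                stats.hmean([m.precision, m.sensitivity]))


class TestAuroc:
    def test_worked_example(self):
        assert ms.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert ms.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_label_inversion_complement(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        assert ms.auroc(s, 1 - y) == pytest.approx(1 - ms.auroc(s, y))

    def test_single_class_undefined(self):
        assert ms.auroc([0.1, 0.9], [1, 1]) is None

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert ms.auroc(np.exp(3 * s), y) == pytest.approx(ms.auroc(s, y))

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 50))
            s = np.round(rng.random(n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            assert ms.auroc(s, y) == pytest.approx(brute_force_auroc(s, y))


class TestAuprc:
    def test_perfect_separation(self):
        assert ms.auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_positive_ranked_first(self):
        assert ms.auprc([0.9, 0.3, 0.2, 0.1], [1, 0, 0, 0]) == 1.0

    def test_no_positives_undefined(self):
        assert ms.auprc([0.1, 0.9], [0, 0]) is None

    def test_random_scores_approach_prevalence(self, rng):
        n, p = 4000, 0.2
        y = (rng.random(n) < p).astype(int)
        s = rng.random(n)
        assert ms.auprc(s, y) == pytest.approx(y.mean(), abs=0.05)


class TestBalancedResampling:
    @staticmethod
    def _table(pos_scores, neg_scores):
        import pandas as pd
        return pd.DataFrame({
            "ensemble": np.concatenate([pos_scores, neg_scores]),
            "label": np.concatenate([np.ones(len(pos_scores), dtype=int),
                                     np.zeros(len(neg_scores), dtype=int)]),
        })

    def test_degenerate_pool_every_rep_identical(self, rng):
        pos = rng.random(20)
        neg = rng.random(20)
        table = self._table(pos, neg)
        rep = ms.balanced_resampling_validation(table, [0.5], n_reps=25,
                                                n_sample=20, seed=0)
        single = ms.evaluate_scores(table["ensemble"], table["label"], 0.5)
        c = rep.mean_counts[0.5]
        assert c.fp == float(np.sum(neg >= 0.5))
        assert rep.counts_metrics[0.5].accuracy == pytest.approx(single.accuracy)
        assert np.allclose(rep.convergence[0.5], c.fp)

    def test_perfectly_separated_scores(self):
        table = self._table(np.ones(10), np.zeros(100))
        rep = ms.balanced_resampling_validation(table, [0.5, 1.0], n_reps=10,
                                                n_sample=10, seed=1)
        for th in (0.5, 1.0):
            c = rep.mean_counts[th]
            assert (c.tp, c.fn, c.fp, c.tn) == (10.0, 0.0, 0.0, 10.0)

    def test_tp_plus_fn_constant_across_thresholds(self, screen_table):
        rep = ms.balanced_resampling_validation(
            screen_table, [0.5, 0.6, 0.7, 0.8, 0.9, 0.95], n_reps=40, seed=3)
        n_pos = int((screen_table["label"] == 1).sum())
        for th in rep.thresholds:
            c = rep.mean_counts[th]
            assert c.tp + c.fn == pytest.approx(n_pos)
            assert c.tn + c.fp == pytest.approx(rep.n_sample)

    def test_tp_antimonotone_in_threshold(self, screen_table):
        rep = ms.balanced_resampling_validation(
            screen_table, [0.3, 0.5, 0.7, 0.9], n_reps=10, seed=3)
        tps = [rep.mean_counts[t].tp for t in (0.3, 0.5, 0.7, 0.9)]
        assert tps == sorted(tps, reverse=True)

    def test_fp_matches_hypergeometric_expectation(self, rng):
        # deterministic scores; sampling 40 of a pool with known FP rate
        neg = np.concatenate([np.full(120, 0.9), np.full(280, 0.1)])
        rng.shuffle(neg)
        table = self._table(np.ones(40), neg)
        n_reps, n_sample = 600, 40
        rep = ms.balanced_resampling_validation(table, [0.5], n_reps=n_reps,
                                                n_sample=n_sample, seed=9)
        expect = n_sample * 120 / 400
        var = (n_sample * (120 / 400) * (280 / 400) * (400 - n_sample) / 399)
        se = np.sqrt(var / n_reps)
        assert abs(rep.mean_counts[0.5].fp - expect) <= 3 * se

    def test_sample_larger_than_pool_rejected(self, rng):
        table = self._table(rng.random(5), rng.random(10))
        with pytest.raises(ValueError):
            ms.balanced_resampling_validation(table, [0.5], n_reps=2, n_sample=11)

    def test_undefined_metrics_excluded_and_counted(self):
        # no positive predictions at threshold 1.0 > all scores: tp=0 and fp=0
        table = self._table(np.full(5, 0.2), np.full(50, 0.1))
        rep = ms.balanced_resampling_validation(table, [0.9], n_reps=8,
                                                n_sample=5, seed=2)
        assert rep.mean_metrics[0.9].precision is None
        assert rep.exclusions[0.9]["precision"] == 8

    def test_deterministic_per_seed(self, screen_table):
        a = ms.balanced_resampling_validation(screen_table, [0.5], n_reps=20, seed=4)
        b = ms.balanced_resampling_validation(screen_table, [0.5], n_reps=20, seed=4)
        assert a.mean_counts[0.5] == b.mean_counts[0.5]
        assert a.mean_metrics[0.5].accuracy == b.mean_metrics[0.5].accuracy

    def test_report_frame_shape(self, screen_table):
        rep = ms.balanced_resampling_validation(
            screen_table, [0.5, 0.6], n_reps=5, seed=0)
        frame = rep.to_frame()
        assert list(frame.columns) == ["threshold", "TP", "FN", "TN", "FP",
                                       "accuracy", "precision", "sensitivity",
                                       "specificity", "F1"]
        assert len(frame) == 2


class TestEvaluateModelOnTest:
    def test_constant_half_scores_give_auroc_half(self):
        m = ms.evaluate_scores(np.full(20, 0.5), [1] * 10 + [0] * 10)
        assert m.auroc == pytest.approx(0.5)

    def test_perfect_oracle_scores_give_f1_one(self):
        m = ms.evaluate_scores([0.9] * 5 + [0.1] * 5, [1] * 5 + [0] * 5)
        assert m.f1 == 1.0 and m.auroc == 1.0 and m.auprc == 1.0
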