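"""Metrics, their brute-force oracles, CIs, calibration and summaries."""

import numpy as np
import pytest
from scipy import stats

from vesselage.evaluate import (
    MetricsReport,
    auc_precision_recall,
    confusion_metrics,
    fold_ci95,
    pick_best,
    reliability_curve,
    summarize_folds,
    summarize_unlabelled,
)
from vesselage.network import AgePrediction
from vesselage.stratify import StratifiedPrediction


def _preds(scores, labels, regions=None, sexes=None):
    return [
        AgePrediction(
            image_id=f"p{i}",
            score=float(s),
            true_label="aged" if l == 1 else "young",
            region=None if regions is None else regions[i],
            sex=None if sexes is None else sexes[i],
        )
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


def _brute_force_ap(scores, labels):
    """Step-wise average precision computed from first principles."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    tp = np.cumsum(y)
    precision = tp / (np.arange(len(y)) + 1)
    return float(np.sum(precision * y) / y.sum())


class TestConfusionMetrics:
    def test_worked_example(self):
        # TP=7, FN=2, TN=8, FP=2
        scores = [0.9] * 7 + [0.1] * 2 + [0.1] * 8 + [0.9] * 2
        labels = [1] * 9 + [0] * 10
        rep = confusion_metrics(_preds(scores, labels))
        assert rep.sensitivity == pytest.approx(77.8, abs=0.05)
        assert rep.specificity == pytest.approx(80.0, abs=0.05)

    def test_all_correct(self):
        rep = confusion_metrics(_preds([0.9, 0.9, 0.1], [1, 1, 0]))
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_undefined_precision_is_absent(self):
        # no positive calls at all: precision has a zero denominator
        rep = confusion_metrics(_preds([0.1, 0.2], [1, 0]))
        assert rep.precision is None
        assert rep.sensitivity == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([])

    def test_unlabelled_rejected(self):
        p = AgePrediction("x", 0.5, true_label=None)
        with pytest.raises(ValueError, match="label"):
            confusion_metrics([p])

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            rep = confusion_metrics(_preds(scores, labels))
            yhat = scores >= 0.5
            tp = np.sum(yhat & (labels == 1))
            fn = np.sum(~yhat & (labels == 1))
            tn = np.sum(~yhat & (labels == 0))
            fp = np.sum(yhat & (labels == 0))
            for got, num, den in [
                (rep.sensitivity, tp, tp + fn),
                (rep.specificity, tn, tn + fp),
                (rep.precision, tp, tp + fp),
            ]:
                if den == 0:
                    assert got is None
                else:
                    assert got == pytest.approx(100 * num / den)


class TestAUPRC:
    def test_perfect_separation(self):
        assert auc_precision_recall(_preds([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 100.0

    def test_reversed_scores_below_prevalence(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        scores = 1.0 - labels * 0.9 - rng.random(n) * 0.05
        val = auc_precision_recall(_preds(scores, labels))
        assert val < 100 * labels.mean()

    def test_label_independent_scores_near_prevalence(self, rng):
        n = 20000
        labels = (rng.random(n) < 0.45).astype(int)
        scores = rng.random(n)
        val = auc_precision_recall(_preds(scores, labels))
        assert val == pytest.approx(45.0, abs=1.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_precision_recall(_preds([0.4, 0.6], [1, 1]))

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = auc_precision_recall(_preds(scores, labels))
            assert got == pytest.approx(100 * _brute_force_ap(scores, labels), abs=1e-9)

    def test_invariant_to_monotone_transforms(self, rng):
        n = 50
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        base = auc_precision_recall(_preds(scores, labels))
        for f in (np.sqrt, lambda s: s**3, lambda s: 1 / (1 + np.exp(-5 * (s - 0.5)))):
            assert auc_precision_recall(_preds(f(scores), labels)) == pytest.approx(base)


class TestFoldAggregation:
    def test_equal_folds_zero_width_ci(self):
        lo, hi = fold_ci95([70.0] * 10)
        assert lo == hi == 70.0

    def test_ci_matches_t_formula(self):
        vals = [60.0, 70.0, 65.0, 75.0, 80.0]
        lo, hi = fold_ci95(vals)
        mean = np.mean(vals)
        half = stats.t.ppf(0.975, 4) * np.std(vals, ddof=1) / np.sqrt(5)
        assert lo == pytest.approx(mean - half)
        assert hi == pytest.approx(mean + half)

    def test_summarize_folds_mean_is_exact(self):
        folds = [
            _preds([0.9, 0.1, 0.6], [1, 0, 0]),
            _preds([0.8, 0.7, 0.2], [1, 0, 0]),
        ]
        rep = summarize_folds(folds)
        per = [confusion_metrics(f).sensitivity for f in folds]
        assert rep.sensitivity == pytest.approx(np.mean(per))
        assert len(rep.per_fold) == 2
        lo, hi = rep.ci95["sensitivity"]
        assert lo <= rep.sensitivity <= hi


class TestPickBest:
    def test_highest_auprc_wins(self):
        reports = [
            MetricsReport(sensitivity=67.6, auc_pr=76.7),
            MetricsReport(sensitivity=69.4, auc_pr=72.8),
        ]
        assert pick_best(reports) == 0

    def test_tie_broken_by_sensitivity(self):
        reports = [
            MetricsReport(sensitivity=60.3, auc_pr=73.7),
            MetricsReport(sensitivity=67.6, auc_pr=73.7),
        ]
        assert pick_best(reports) == 1

    def test_full_tie_prefers_first_listed(self):
        reports = [
            MetricsReport(sensitivity=60.0, auc_pr=70.0),
            MetricsReport(sensitivity=60.0, auc_pr=70.0),
        ]
        assert pick_best(reports) == 0


class TestReliabilityCurve:
    def test_calibrated_scores_follow_diagonal(self, rng):
        n = 20000
        scores = rng.random(n)
        labels = (rng.random(n) < scores).astype(int)
        curve = reliability_curve(_preds(scores, labels), n_bins=10)
        for mp, of, c in zip(
            curve.bin_mean_predicted, curve.bin_observed_frequency, curve.bin_counts
        ):
            assert c > 0
            assert of == pytest.approx(mp, abs=0.04)

    def test_degenerate_single_bin(self):
        curve = reliability_curve(_preds([1.0, 1.0, 1.0], [1, 1, 1]), n_bins=5)
        assert curve.bin_counts[-1] == 3
        assert curve.bin_mean_predicted[-1] == 1.0
        assert curve.bin_observed_frequency[-1] == 1.0
        assert curve.bin_counts[:-1] == [0] * 4

    def test_empty_bins_reported_absent(self):
        curve = reliability_curve(_preds([0.05, 0.95], [0, 1]), n_bins=10)
        assert sum(curve.bin_counts) == 2
        for i, c in enumerate(curve.bin_counts):
            if c == 0:
                assert curve.bin_observed_frequency[i] is None

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            reliability_curve(_preds([0.5], [1]), n_bins=1)


class TestSummarizeUnlabelled:
    def _strat(self, region_groups):
        out = []
        for i, (region, group) in enumerate(region_groups):
            score = {"Red": 0.9, "Amber": 0.5, "Green": 0.1}[group]
            p = AgePrediction(f"u{i}", score, true_label=None, region=region)
            out.append(StratifiedPrediction(p, group))
        return out

    def test_region_percentage_breakdown(self):
        # 29 images: 16 confident aged, 4 confident young, 9 uncertain
        rows = [("CC", "Red")] * 16 + [("CC", "Green")] * 4 + [("CC", "Amber")] * 9
        table = summarize_unlabelled(self._strat(rows))
        row = table[table.region == "CC"].iloc[0]
        assert row.total_images == 29
        assert row.pct_aged == pytest.approx(55.2, abs=0.05)
        assert row.pct_young == pytest.approx(13.8, abs=0.05)
        assert row.pct_uncertain == pytest.approx(31.0, abs=0.05)
        assert row.pct_aged + row.pct_young + row.pct_uncertain == pytest.approx(100.0)

    def test_all_uncertain(self):
        table = summarize_unlabelled(self._strat([("HC", "Amber")] * 5))
        row = table.iloc[0]
        assert (row.pct_aged, row.pct_young, row.pct_uncertain) == (0.0, 0.0, 100.0)

    def test_empty_region_absent(self):
        table = summarize_unlabelled(self._strat([("CC", "Red"), ("PFC", "Green")]))
        assert set(table.region) == {"CC", "PFC"}


class TestCrossValidationHarness:
    def test_validation_never_enters_augmented_fit_set(self, small_cohort):
        """Per fold: the fit portion is augmented, the validation portion is
        scored un-augmented, and no validation image leaks into the fit set."""
        from vesselage.augment import augment_training_set
        from vesselage.core_data import PipelineConfig, make_cv_folds, subseed
        from vesselage.evaluate import run_cv_predictions
        from vesselage.network import BackboneSpec, HeadConfig, TrainConfig

        train = small_cohort["manifest"].labelled()
        cfg = PipelineConfig(seed=3)
        tc = TrainConfig(epochs=1, learning_rate=2e-3, seed=3)
        k = 2
        fold_preds = run_cv_predictions(
            train, BackboneSpec("tiny_test"), HeadConfig(), tc, cfg, k
        )
        # validation sets partition the training manifest
        val_ids = [sorted(p.image_id for p in fold) for fold in fold_preds]
        assert sorted(i for ids in val_ids for i in ids) == sorted(
            r.image_id for r in train
        )
        # rebuild each fold's augmented fit set exactly as the harness does
        folds = make_cv_folds(train, k, seed=subseed(cfg.seed, f"folds{k}"))
        from vesselage.evaluate import prepare_items

        items = prepare_items(train, cfg, {})
        for f, (fit_idx, _val_idx) in enumerate(folds):
            augset = augment_training_set(
                [items[i] for i in fit_idx],
                cfg,
                seed=subseed(cfg.seed, f"aug{k}.{f}"),
                ids=[train.records[i].image_id for i in fit_idx],
            )
            fit_sources = {src for src, _t in augset.provenance}
            assert fit_sources.isdisjoint(val_ids[f])
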