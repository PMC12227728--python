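"""Traffic-light stratification: assignment, optimisation, subgroup scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselage.evaluate import confusion_metrics
from vesselage.network import AgePrediction
from vesselage.stratify import (
    StratificationThresholds,
    StratifiedPrediction,
    assign_group,
    evaluate_thresholds,
    group_difference_score,
    optimize_thresholds_on_predictions,
    post_stratification_metrics,
    stratify_predictions,
)


def _preds(scores, labels, sexes=None, regions=None):
    return [
        AgePrediction(
            image_id=f"p{i}",
            score=float(s),
            true_label="aged" if l == 1 else "young",
            sex=None if sexes is None else sexes[i],
            region=None if regions is None else regions[i],
        )
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


class TestAssignGroup:
    TH = StratificationThresholds(0.25, 0.75)

    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.10, "Green"),
            (0.25, "Amber"),  # boundary belongs to the upper band
            (0.50, "Amber"),
            (0.75, "Red"),  # boundary belongs to Red
            (0.80, "Red"),
            (0.0, "Green"),
            (1.0, "Red"),
        ],
    )
    def test_boundary_convention(self, score, expected):
        assert assign_group(score, self.TH) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_group(1.2, self.TH)

    def test_degenerate_thresholds_reproduce_argmax(self, rng):
        th = StratificationThresholds(0.5, 0.5)
        for score in rng.random(200):
            group = assign_group(float(score), th)
            assert group == ("Red" if score >= 0.5 else "Green")
            assert group != "Amber"

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            StratificationThresholds(0.8, 0.2)
        with pytest.raises(ValueError):
            StratificationThresholds(0.0, 0.5)

    @settings(max_examples=200, deadline=None)
    @given(
        score=st.floats(0.0, 1.0),
        t_low=st.floats(0.05, 0.95),
        width=st.floats(0.0, 0.9),
    )
    def test_exactly_one_group(self, score, t_low, width):
        t_high = min(max(t_low + width, t_low), 0.95)
        th = StratificationThresholds(t_low, t_high)
        assert assign_group(score, th) in ("Green", "Amber", "Red")

    def test_partition_counts(self, rng):
        scores = rng.random(500)
        th = StratificationThresholds(0.3, 0.7)
        groups = [assign_group(float(s), th) for s in scores]
        counts = {g: groups.count(g) for g in ("Green", "Amber", "Red")}
        assert sum(counts.values()) == 500


class TestPostStratificationMetrics:
    def test_worked_example(self):
        # 9 aged: 7 Red, 2 Green; 10 young: 8 Green, 2 Red; 3 Amber extras
        strat = []
        for label, group, n in [
            ("aged", "Red", 7),
            ("aged", "Green", 2),
            ("young", "Green", 8),
            ("young", "Red", 2),
            ("aged", "Amber", 2),
            ("young", "Amber", 1),
        ]:
            score = {"Red": 0.9, "Green": 0.1, "Amber": 0.5}[group]
            for i in range(n):
                p = AgePrediction(f"{label}{group}{i}", score, true_label=label)
                strat.append(StratifiedPrediction(p, group))
        rep, amber = post_stratification_metrics(strat)
        assert rep.sensitivity == pytest.approx(77.8, abs=0.05)
        assert rep.specificity == pytest.approx(80.0, abs=0.05)
        assert rep.precision == pytest.approx(77.8, abs=0.05)
        assert rep.n_evaluated == 19
        assert amber == pytest.approx(3 / 22)

    def test_no_amber_reduces_to_plain_metrics(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        preds = _preds(scores, labels)
        strat = stratify_predictions(preds, StratificationThresholds(0.5, 0.5))
        rep, amber = post_stratification_metrics(strat)
        plain = confusion_metrics(preds)
        assert amber == 0.0
        assert rep.sensitivity == plain.sensitivity
        assert rep.specificity == plain.specificity

    def test_all_amber_absent_metrics(self):
        preds = _preds([0.5, 0.5], [1, 0])
        strat = stratify_predictions(preds, StratificationThresholds(0.4, 0.6))
        rep, amber = post_stratification_metrics(strat)
        assert amber == 1.0
        assert rep.sensitivity is None and rep.specificity is None


class TestOptimizeThresholds:
    @staticmethod
    def _pooled(rng, n=300):
        labels = rng.integers(0, 2, n)
        scores = np.where(
            labels == 1, rng.beta(5, 2, n), rng.beta(2, 5, n)
        )
        return _preds(scores, labels)

    def test_matches_exhaustive_grid_search(self, rng):
        # independent oracle: brute-force every lattice pair with the same
        # objective and feasibility rule
        preds = self._pooled(rng)
        amber_cap = 0.35
        got = optimize_thresholds_on_predictions(preds, amber_cap=amber_cap)
        ticks = np.round(np.arange(0.05, 0.975, 0.05), 10)
        best_obj, best_amber = -1.0, None
        for lo in ticks:
            for hi in ticks:
                if hi < lo:
                    continue
                obj, amber = evaluate_thresholds(
                    preds, StratificationThresholds(float(lo), float(hi))
                )
                if obj is None or amber > amber_cap:
                    continue
                if obj > best_obj or (obj == best_obj and amber < best_amber):
                    best_obj, best_amber = obj, amber
        got_obj, got_amber = evaluate_thresholds(preds, got)
        assert got_obj == pytest.approx(best_obj)
        assert got_amber <= best_amber + 1e-12

    def test_improves_on_unstratified_decision(self, rng):
        preds = self._pooled(rng)
        got = optimize_thresholds_on_predictions(preds, amber_cap=0.35)
        post_obj, _ = evaluate_thresholds(preds, got)
        pre_obj, _ = evaluate_thresholds(preds, StratificationThresholds(0.5, 0.5))
        assert post_obj >= pre_obj

    def test_zero_cap_degenerates_to_single_threshold(self, rng):
        preds = self._pooled(rng)
        th = optimize_thresholds_on_predictions(preds, amber_cap=0.0)
        assert th.t_low == th.t_high

    def test_perfect_separation_minimal_amber(self):
        preds = _preds([0.9] * 10 + [0.1] * 10, [1] * 10 + [0] * 10)
        th = optimize_thresholds_on_predictions(preds, amber_cap=0.5)
        obj, amber = evaluate_thresholds(preds, th)
        assert obj == 1.0
        assert amber == 0.0

    def test_order_invariance(self, rng):
        preds = self._pooled(rng, n=120)
        shuffled = list(preds)
        rng.shuffle(shuffled)
        assert optimize_thresholds_on_predictions(preds) == (
            optimize_thresholds_on_predictions(shuffled)
        )

    def test_infeasible_pool_raises(self):
        only_aged = _preds([0.9, 0.8], [1, 1])
        with pytest.raises(ValueError, match="cap"):
            optimize_thresholds_on_predictions(only_aged)

    def test_raising_t_high_never_lowers_specificity(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        preds = _preds(scores, labels)

        def confident_specificity(th):
            strat = stratify_predictions(preds, th)
            labels_ = np.array(
                [1 if s.prediction.true_label == "aged" else 0 for s in strat]
            )
            groups = np.array([s.group for s in strat])
            tn = np.sum((labels_ == 0) & (groups == "Green"))
            fp = np.sum((labels_ == 0) & (groups == "Red"))
            return tn / (tn + fp) if tn + fp else None

        for hi1, hi2 in [(0.5, 0.7), (0.6, 0.9), (0.3, 0.4)]:
            s1 = confident_specificity(StratificationThresholds(0.3, hi1))
            s2 = confident_specificity(StratificationThresholds(0.3, hi2))
            if s1 is not None and s2 is not None:
                assert s2 >= s1


class TestGroupDifferenceScore:
    def test_sex_difference_worked_example(self):
        # male confident-aged mean 90.1%, confident-young mean 15.6%
        scores = [0.91, 0.892, 0.14, 0.172, 0.9, 0.2]
        labels = [1, 1, 0, 0, 1, 0]
        sexes = ["M", "M", "M", "M", "F", "F"]
        preds = _preds(scores, labels, sexes=sexes)
        strat = stratify_predictions(preds, StratificationThresholds(0.25, 0.75))
        table = group_difference_score(strat, by="sex")
        male = table[table.sex == "M"].iloc[0]
        assert male.mean_aged_score == pytest.approx(90.1, abs=0.05)
        assert male.mean_young_score == pytest.approx(15.6, abs=0.05)
        assert male.difference == pytest.approx(74.5, abs=0.05)

    def test_region_difference_worked_example(self):
        scores = [0.874, 0.125, 0.9, 0.1]
        labels = [1, 0, 1, 0]
        regions = ["PFC", "PFC", "CC", "CC"]
        preds = _preds(scores, labels, regions=regions)
        strat = stratify_predictions(preds, StratificationThresholds(0.25, 0.75))
        table = group_difference_score(strat, by="region")
        pfc = table[table.region == "PFC"].iloc[0]
        assert pfc.difference == pytest.approx(74.9, abs=0.05)

    def test_missing_confident_group_gives_absent_difference(self):
        preds = _preds([0.9, 0.95], [1, 1], sexes=["F", "F"])
        strat = stratify_predictions(preds, StratificationThresholds(0.25, 0.75))
        table = group_difference_score(strat, by="sex")
        assert np.isnan(table.iloc[0].difference)

    def test_invalid_grouping_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            group_difference_score([], by="mouse")
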