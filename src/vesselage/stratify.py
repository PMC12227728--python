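"""Traffic-light stratification of age-likelihood scores.

Scores are partitioned by two thresholds into Green (confident young,
``score < t_low``), Amber (uncertain, ``t_low <= score < t_high``) and Red
(confident aged, ``score >= t_high``).  The half-open boundary convention
resolves the ambiguity of overlapping interval notation: 0.25 with
thresholds (0.25, 0.75) is Amber, 0.75 is Red.  Thresholds are optimised on
pooled out-of-fold validation predictions from a 5-fold cross-validation,
maximising the smaller of sensitivity and specificity computed on the
confident (Green + Red) predictions, subject to a cap on the Amber
fraction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import DatasetManifest, PipelineConfig
from .evaluate import MetricsReport, run_cv_predictions
from .network import AgePrediction, BackboneSpec, HeadConfig, TrainConfig

logger = logging.getLogger(__name__)

GROUPS = ("Green", "Amber", "Red")


@dataclass(frozen=True)
class StratificationThresholds:
    """The (t_low, t_high) pair defining the Green/Amber/Red bands."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t_low <= self.t_high < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < t_low <= t_high < 1; got "
                f"({self.t_low}, {self.t_high})"
            )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"t_low": self.t_low, "t_high": self.t_high}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "StratificationThresholds":
        d = json.loads(Path(path).read_text())
        return cls(t_low=d["t_low"], t_high=d["t_high"])


@dataclass
class StratifiedPrediction:
    """An age prediction together with its traffic-light group."""

    prediction: AgePrediction
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def assign_group(score: float, th: StratificationThresholds) -> str:
    """Green if score < t_low; Amber if t_low <= score < t_high; else Red."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < th.t_low:
        return "Green"
    if score < th.t_high:
        return "Amber"
    return "Red"


def stratify_predictions(
    preds: Sequence[AgePrediction], th: StratificationThresholds
) -> list[StratifiedPrediction]:
    return [StratifiedPrediction(p, assign_group(p.score, th)) for p in preds]


def _confident_confusion(
    labels: np.ndarray, groups: np.ndarray
) -> tuple[int, int, int, int, float]:
    """(tp, fn, tn, fp, amber_fraction) with Red = predicted aged, Green =
    predicted young, Amber excluded from the confusion counts."""
    amber = groups == "Amber"
    tp = int(np.sum((labels == 1) & (groups == "Red")))
    fn = int(np.sum((labels == 1) & (groups == "Green")))
    tn = int(np.sum((labels == 0) & (groups == "Green")))
    fp = int(np.sum((labels == 0) & (groups == "Red")))
    amber_fraction = float(amber.mean()) if len(groups) else 0.0
    return tp, fn, tn, fp, amber_fraction


def post_stratification_metrics(
    preds: Sequence[StratifiedPrediction],
) -> tuple[MetricsReport, float]:
    """Confusion metrics on the confident groups plus the Amber fraction.

    Red counts as a positive (aged) call and Green as a negative (young)
    call; Amber predictions are abstentions and enter only the reported
    ``amber_fraction``.  If everything is Amber the metrics are absent.
    """
    if not preds:
        raise ValueError("cannot compute metrics on an empty prediction list")
    labels = np.array(
        [1 if sp.prediction.true_label == "aged" else 0 for sp in preds]
    )
    for sp in preds:
        if sp.prediction.true_label not in ("aged", "young"):
            raise ValueError("post-stratification metrics require labelled predictions")
    groups = np.array([sp.group for sp in preds])
    tp, fn, tn, fp, amber_fraction = _confident_confusion(labels, groups)

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    report = MetricsReport(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp),
        n_evaluated=int((groups != "Amber").sum()),
    )
    return report, amber_fraction


def _grid(step: float) -> list[StratificationThresholds]:
    ticks = np.round(np.arange(step, 1.0 - step / 2, step), 10)
    return [
        StratificationThresholds(float(lo), float(hi))
        for lo, hi in itertools.combinations_with_replacement(ticks, 2)
    ]


def evaluate_thresholds(
    preds: Sequence[AgePrediction], th: StratificationThresholds
) -> tuple[float | None, float]:
    """(min(sensitivity, specificity) on the confident set, amber fraction).

    Returns ``None`` for the objective when either metric is undefined.
    """
    labels = np.array([1 if p.true_label == "aged" else 0 for p in preds])
    groups = np.array([assign_group(p.score, th) for p in preds])
    tp, fn, tn, fp, amber_fraction = _confident_confusion(labels, groups)
    if tp + fn == 0 or tn + fp == 0:
        return None, amber_fraction
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(min(sens, spec)), amber_fraction


def optimize_thresholds_on_predictions(
    preds: Sequence[AgePrediction],
    amber_cap: float = 0.35,
    step: float = 0.05,
) -> StratificationThresholds:
    """Exhaustive lattice search for the best (t_low, t_high) pair.

    Maximises min(sensitivity, specificity) over the confident predictions
    subject to ``amber_fraction <= amber_cap``.  Ties prefer a smaller Amber
    fraction, then a wider band symmetric about 0.5.
    """
    if not 0.0 <= amber_cap < 1.0:
        raise ValueError("amber_cap must lie in [0, 1)")
    best: tuple | None = None
    best_th: StratificationThresholds | None = None
    for th in _grid(step):
        objective, amber = evaluate_thresholds(preds, th)
        if objective is None or amber > amber_cap + 1e-12:
            continue
        width = th.t_high - th.t_low
        asym = abs(th.t_low + th.t_high - 1.0)
        key = (objective, -amber, width, -asym, -th.t_low)
        if best is None or key > best:
            best, best_th = key, th
    if best_th is None:
        raise ValueError(
            f"no feasible thresholds under amber_cap={amber_cap}; "
            "try a larger cap"
        )
    logger.info(
        "optimal thresholds (%.2f, %.2f): min(sens,spec)=%.3f amber=%.3f",
        best_th.t_low, best_th.t_high, best[0], -best[1],
    )
    return best_th


def optimize_thresholds(
    train: DatasetManifest,
    backbone: BackboneSpec,
    head: HeadConfig,
    tc: TrainConfig,
    cfg: PipelineConfig,
    amber_cap: float = 0.35,
    step: float = 0.05,
    image_cache: dict | None = None,
) -> StratificationThresholds:
    """Optimise thresholds on pooled out-of-fold validation predictions.

    Runs a k-fold cross-validation (k = ``cfg.threshold_folds``) with the
    selected model recipe, pools the validation predictions of all folds,
    and grid-searches the threshold lattice on the pooled set.
    """
    fold_preds = run_cv_predictions(
        train, backbone, head, tc, cfg, cfg.threshold_folds, image_cache
    )
    pooled = [p for fold in fold_preds for p in fold]
    # order invariance: the grid search consumes the pool as a set of
    # (score, label) pairs, so pooling order cannot matter
    return optimize_thresholds_on_predictions(pooled, amber_cap=amber_cap, step=step)


def group_difference_score(
    preds: Sequence[StratifiedPrediction], by: str
) -> "pd.DataFrame":
    """Mean confident-aged and confident-young scores, and their gap.

    Per subgroup of ``by`` (``sex`` or ``region``): the mean score of
    Red-assigned images, the mean score of Green-assigned images, and their
    difference, all as percentages.  A subgroup missing either confident
    group has an absent (NaN) difference.
    """
    import pandas as pd

    if by not in ("sex", "region"):
        raise ValueError("by must be 'sex' or 'region'")
    groups: dict[str, dict[str, list[float]]] = {}
    for sp in preds:
        key = getattr(sp.prediction, by)
        if key is None:
            raise ValueError(f"prediction {sp.prediction.image_id!r} lacks {by}")
        groups.setdefault(key, {"Red": [], "Green": []})
        if sp.group in ("Red", "Green"):
            groups[key][sp.group].append(sp.prediction.score)
    rows = []
    for key in sorted(groups):
        reds, greens = groups[key]["Red"], groups[key]["Green"]
        mean_red = 100.0 * float(np.mean(reds)) if reds else np.nan
        mean_green = 100.0 * float(np.mean(greens)) if greens else np.nan
        diff = mean_red - mean_green if reds and greens else np.nan
        rows.append(
            {
                by: key,
                "mean_aged_score": mean_red,
                "mean_young_score": mean_green,
                "difference": diff,
            }
        )
    return pd.DataFrame(rows)


def export_stratified_csv(
    preds: Sequence[StratifiedPrediction], path: str | Path
) -> None:
    """Write stratified predictions (id, score, group, label, sex, region)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "image_id": sp.prediction.image_id,
                "score": sp.prediction.score,
                "group": sp.group,
                "label": sp.prediction.true_label,
                "sex": sp.prediction.sex,
                "region": sp.prediction.region,
            }
            for sp in preds
        ]
    ).to_csv(path, index=False)
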