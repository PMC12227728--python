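"""Cross-validation harness, classification metrics and calibration.

Metrics follow the usual binary conventions with *aged* as the positive
class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
TP/(TP+FP), all reported as percentages.  The ranking metric is the area
under the precision-recall curve (AUPRC) computed with the step-wise
estimator (no linear interpolation between operating points).  Fold-level
means carry 95% confidence intervals based on the t distribution with k-1
degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .augment import augment_training_set
from .core_data import (
    DatasetManifest,
    PipelineConfig,
    encode_metadata,
    make_cv_folds,
    subseed,
)
from .network import (
    AgePrediction,
    BackboneSpec,
    HeadConfig,
    TrainConfig,
    build_model,
    predict_batch,
    train_head,
)
from .preprocess import load_image, to_model_image

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Percent-scale classification metrics with optional fold breakdown."""

    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    auc_pr: float | None = None
    n_evaluated: int = 0
    per_fold: list["MetricsReport"] | None = None
    ci95: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc_pr": self.auc_pr,
            "n_evaluated": self.n_evaluated,
        }
        if self.ci95 is not None:
            out["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        return out


@dataclass
class ReliabilityCurve:
    """Binned agreement between predicted scores and observed frequency."""

    bin_edges: np.ndarray
    bin_mean_predicted: list[float | None]
    bin_observed_frequency: list[float | None]
    bin_counts: list[int]


def _labels01(preds: Sequence[AgePrediction]) -> np.ndarray:
    labels = []
    for p in preds:
        if p.true_label not in ("aged", "young"):
            raise ValueError(f"prediction {p.image_id!r} has no usable label")
        labels.append(1 if p.true_label == "aged" else 0)
    return np.asarray(labels)


def confusion_metrics(
    preds: Sequence[AgePrediction], threshold: float = 0.5
) -> MetricsReport:
    """Threshold the scores and compute sensitivity/specificity/precision.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    if not preds:
        raise ValueError("cannot compute metrics on an empty prediction list")
    y = _labels01(preds)
    yhat = np.array([1 if p.score >= threshold else 0 for p in preds])
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return MetricsReport(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp),
        n_evaluated=len(preds),
    )


def auc_precision_recall(preds: Sequence[AgePrediction]) -> float:
    """Step-wise area under the precision-recall curve, in percent."""
    y = _labels01(preds)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC requires both classes to be present")
    scores = np.array([p.score for p in preds])
    return 100.0 * float(average_precision_score(y, scores))


def fold_ci95(values: Sequence[float]) -> tuple[float, float]:
    """Mean +/- t(0.975, k-1) * sd / sqrt(k) over per-fold values."""
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    k = len(vals)
    mean = float(vals.mean())
    if k < 2:
        return mean, mean
    half = float(stats.t.ppf(0.975, k - 1) * vals.std(ddof=1) / np.sqrt(k))
    return mean - half, mean + half


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def prepare_items(
    manifest: DatasetManifest,
    cfg: PipelineConfig,
    cache: dict | None = None,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Load and preprocess every record into (model image, metadata, label).

    Unlabelled records receive label -1.  ``cache`` (path -> model image)
    avoids re-running the preprocessing chain across folds.
    """
    items = []
    for rec in manifest.records:
        key = str(rec.path)
        if cache is not None and key in cache:
            img = cache[key]
        else:
            img = to_model_image(load_image(rec.path), cfg)
            if cache is not None:
                cache[key] = img
        label = {"aged": 1, "young": 0}.get(rec.age_label, -1)
        items.append((img, encode_metadata(rec), label))
    return items


def run_cv_predictions(
    train: DatasetManifest,
    backbone: BackboneSpec,
    head: HeadConfig,
    tc: TrainConfig,
    cfg: PipelineConfig,
    k: int,
    image_cache: dict | None = None,
) -> list[list[AgePrediction]]:
    """Train on each fold's fit portion (8x augmented) and predict its
    un-augmented validation portion; returns per-fold prediction lists."""
    folds = make_cv_folds(train, k, seed=subseed(cfg.seed, f"folds{k}"))
    cache = image_cache if image_cache is not None else {}
    items = prepare_items(train, cfg, cache)
    out: list[list[AgePrediction]] = []
    for f, (fit_idx, val_idx) in enumerate(folds):
        fit_items = [items[i] for i in fit_idx]
        fit_ids = [train.records[i].image_id for i in fit_idx]
        augset = augment_training_set(
            fit_items, cfg, seed=subseed(cfg.seed, f"aug{k}.{f}"), ids=fit_ids
        )
        model = build_model(
            backbone, head=head, seed=subseed(cfg.seed, f"init{k}.{f}")
        )
        train_head(model, augset, replace(tc, seed=subseed(tc.seed, f"train{k}.{f}")))
        val_pairs = [(items[i][0], items[i][1]) for i in val_idx]
        scores = predict_batch(model, val_pairs)
        fold_preds = [
            AgePrediction(
                image_id=train.records[i].image_id,
                score=float(s),
                true_label=train.records[i].age_label,
                sex=train.records[i].sex,
                region=train.records[i].region,
            )
            for i, s in zip(val_idx, scores)
        ]
        out.append(fold_preds)
        logger.info("fold %d/%d: %d validation predictions", f + 1, k, len(fold_preds))
    return out


def summarize_folds(fold_preds: Sequence[Sequence[AgePrediction]]) -> MetricsReport:
    """Aggregate per-fold metrics into mean values with 95% CIs."""
    per_fold = []
    for preds in fold_preds:
        rep = confusion_metrics(list(preds))
        rep.auc_pr = auc_precision_recall(list(preds))
        per_fold.append(rep)
    means: dict[str, float | None] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name in ("sensitivity", "specificity", "precision", "auc_pr"):
        vals = [getattr(r, name) for r in per_fold if getattr(r, name) is not None]
        if vals:
            means[name] = float(np.mean(vals))
            ci[name] = fold_ci95(vals)
        else:
            means[name] = None
    return MetricsReport(
        sensitivity=means["sensitivity"],
        specificity=means["specificity"],
        precision=means["precision"],
        auc_pr=means["auc_pr"],
        n_evaluated=sum(len(p) for p in fold_preds),
        per_fold=per_fold,
        ci95=ci,
    )


def cross_validate(
    train: DatasetManifest,
    backbone: BackboneSpec,
    head: HeadConfig,
    tc: TrainConfig,
    cfg: PipelineConfig,
    image_cache: dict | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation (k = cfg.model_selection_folds)."""
    fold_preds = run_cv_predictions(
        train, backbone, head, tc, cfg, cfg.model_selection_folds, image_cache
    )
    return summarize_folds(fold_preds)


def select_model(
    candidates: Sequence[tuple[BackboneSpec, HeadConfig, TrainConfig]],
    train: DatasetManifest,
    cfg: PipelineConfig,
    image_cache: dict | None = None,
) -> tuple[tuple[BackboneSpec, HeadConfig, TrainConfig], list[MetricsReport]]:
    """Cross-validate every candidate and return the mean-AUPRC argmax.

    Ties are broken by higher mean sensitivity, then by listing order.
    """
    if not candidates:
        raise ValueError("need at least one candidate configuration")
    reports = [
        cross_validate(train, b, h, t, cfg, image_cache) for b, h, t in candidates
    ]
    return candidates[pick_best(reports)], reports


def pick_best(reports: Sequence[MetricsReport]) -> int:
    """Index of the winning report: highest mean AUPRC, ties broken by
    higher mean sensitivity, then by listing order."""
    best = 0
    for i in range(1, len(reports)):
        ri, rb = reports[i], reports[best]
        if (ri.auc_pr or 0.0, ri.sensitivity or 0.0) > (rb.auc_pr or 0.0, rb.sensitivity or 0.0):
            best = i
    return best


def reliability_curve(
    preds: Sequence[AgePrediction], n_bins: int = 10
) -> ReliabilityCurve:
    """Equal-width reliability (calibration) curve on [0, 1].

    Per bin: mean predicted score and observed aged fraction; empty bins
    report a count of 0 and absent (None) values.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y = _labels01(preds)
    scores = np.array([p.score for p in preds])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    mean_pred: list[float | None] = []
    obs_freq: list[float | None] = []
    counts: list[int] = []
    for b in range(n_bins):
        mask = idx == b
        counts.append(int(mask.sum()))
        if mask.any():
            mean_pred.append(float(scores[mask].mean()))
            obs_freq.append(float(y[mask].mean()))
        else:
            mean_pred.append(None)
            obs_freq.append(None)
    return ReliabilityCurve(edges, mean_pred, obs_freq, counts)


def summarize_unlabelled(strat_preds: Sequence) -> pd.DataFrame:
    """Per-region percentages of confident-aged / confident-young / uncertain.

    Accepts stratified predictions (objects with ``group`` and a
    ``prediction`` carrying ``region``).  Red counts as predicted aged,
    Green as predicted young, Amber as uncertain; each row's percentages are
    over that region's total and sum to 100 up to rounding.  Regions with no
    images are absent.
    """
    rows = {}
    for sp in strat_preds:
        region = sp.prediction.region
        if region is None:
            raise ValueError("stratified prediction lacks region metadata")
        rows.setdefault(region, {"Red": 0, "Green": 0, "Amber": 0})
        rows[region][sp.group] += 1
    table = []
    for region in sorted(rows):
        c = rows[region]
        total = c["Red"] + c["Green"] + c["Amber"]
        table.append(
            {
                "region": region,
                "total_images": total,
                "pct_aged": 100.0 * c["Red"] / total,
                "pct_young": 100.0 * c["Green"] / total,
                "pct_uncertain": 100.0 * c["Amber"] / total,
            }
        )
    return pd.DataFrame(table)


def plot_reliability(curve: ReliabilityCurve, path) -> None:
    """Save a reliability diagram as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    xs = [m for m in curve.bin_mean_predicted if m is not None]
    ys = [o for o in curve.bin_observed_frequency if o is not None]
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ax.plot(xs, ys, "o-", label="model")
    ax.set_xlabel("mean predicted age likelihood")
    ax.set_ylabel("observed aged fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
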