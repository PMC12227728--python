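"""High-level orchestration of the full analysis on a manifest.

``run_full_pipeline`` reproduces the study workflow on any manifest:
age-stratified 90:10 split, vessel-leakage guard, 8x dihedral augmentation
of the training data, head fine-tuning of the chosen backbone, 5-fold
threshold optimisation on pooled out-of-fold validation predictions, and
held-out-test evaluation before and after traffic-light stratification.

The default recipe uses the ``tiny_test`` backbone with a learning rate of
2e-3 (the backbone is randomly initialised, so it benefits from a larger
step than the 1e-4 transfer-learning default used with pretrained
backbones), 11 epochs and batch size 16.
"""

from __future__ import annotations

from dataclasses import dataclass

from .augment import augment_training_set
from .core_data import (
    DatasetManifest,
    PipelineConfig,
    drop_leaky_test_images,
    stratified_split,
    subseed,
)
from .evaluate import (
    MetricsReport,
    auc_precision_recall,
    confusion_metrics,
    prepare_items,
)
from .network import (
    AgePrediction,
    BackboneSpec,
    FusionModel,
    HeadConfig,
    TrainConfig,
    build_model,
    predict_batch,
    train_head,
)
from .stratify import (
    StratificationThresholds,
    StratifiedPrediction,
    optimize_thresholds,
    post_stratification_metrics,
    stratify_predictions,
)


@dataclass
class PipelineResult:
    """Everything the full run produces, for reporting and assertions."""

    train_manifest: DatasetManifest
    test_manifest: DatasetManifest
    model: FusionModel
    thresholds: StratificationThresholds
    test_predictions: list[AgePrediction]
    stratified: list[StratifiedPrediction]
    metrics_before: MetricsReport
    metrics_after: MetricsReport
    amber_fraction: float


def predictions_for_manifest(
    manifest: DatasetManifest,
    model: FusionModel,
    cfg: PipelineConfig,
    image_cache: dict | None = None,
) -> list[AgePrediction]:
    """Score every record of a manifest in evaluation mode."""
    items = prepare_items(manifest, cfg, image_cache)
    scores = predict_batch(model, [(img, meta) for img, meta, _ in items])
    return [
        AgePrediction(
            image_id=rec.image_id,
            score=float(s),
            true_label=rec.age_label if rec.is_labelled else None,
            sex=rec.sex,
            region=rec.region,
        )
        for rec, s in zip(manifest.records, scores)
    ]


def run_full_pipeline(
    manifest: DatasetManifest,
    seed: int,
    backbone: BackboneSpec | None = None,
    head: HeadConfig | None = None,
    epochs: int = 11,
    batch_size: int = 16,
    learning_rate: float = 2e-3,
    amber_cap: float = 0.35,
    optimize_strata: bool = True,
    image_cache: dict | None = None,
) -> PipelineResult:
    """Split, train, optimise thresholds and evaluate on the held-out test."""
    backbone = backbone or BackboneSpec("tiny_test")
    head = head or HeadConfig()
    cfg = PipelineConfig(seed=seed)
    tc = TrainConfig(
        epochs=epochs, batch_size=batch_size, learning_rate=learning_rate, seed=seed
    )
    cache = image_cache if image_cache is not None else {}

    train_m, test_m = stratified_split(
        manifest, cfg.train_fraction, seed=subseed(seed, "split")
    )
    test_m = drop_leaky_test_images(train_m, test_m)

    # final model: refit on the full training manifest, 8x augmented
    items = prepare_items(train_m, cfg, cache)
    augset = augment_training_set(
        items, cfg, seed=subseed(seed, "aug_final"),
        ids=[r.image_id for r in train_m.records],
    )
    model = build_model(backbone, head=head, seed=subseed(seed, "init_final"))
    train_head(model, augset, tc)

    if optimize_strata:
        thresholds = optimize_thresholds(
            train_m, backbone, head, tc, cfg, amber_cap=amber_cap, image_cache=cache
        )
    else:
        thresholds = StratificationThresholds(0.5, 0.5)

    test_preds = predictions_for_manifest(test_m, model, cfg, cache)
    metrics_before = confusion_metrics(test_preds)
    metrics_before.auc_pr = auc_precision_recall(test_preds)
    stratified = stratify_predictions(test_preds, thresholds)
    metrics_after, amber_fraction = post_stratification_metrics(stratified)
    return PipelineResult(
        train_manifest=train_m,
        test_manifest=test_m,
        model=model,
        thresholds=thresholds,
        test_predictions=test_preds,
        stratified=stratified,
        metrics_before=metrics_before,
        metrics_after=metrics_after,
        amber_fraction=amber_fraction,
    )
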