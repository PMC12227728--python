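"""Shared fixtures: synthetic cohorts and quickly trained models.

All image data is generated programmatically at test time by the package's
own synthetic-capillary module; nothing is read from checked-in files.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselage.augment import augment_training_set
from vesselage.core_data import (
    DatasetManifest,
    ImageRecord,
    PipelineConfig,
)
from vesselage.evaluate import prepare_items
from vesselage.network import (
    BackboneSpec,
    HeadConfig,
    TrainConfig,
    build_model,
    train_head,
)
from vesselage.synthsample import SynthConfig, generate_dataset


def make_records(
    n_aged: int,
    n_young: int,
    n_unlabelled: int = 0,
    vessel_groups: dict[str, str] | None = None,
) -> DatasetManifest:
    """In-memory manifest with the requested class counts (no image files)."""
    records = []
    spec = [("aged", n_aged), ("young", n_young), ("unlabelled", n_unlabelled)]
    i = 0
    for label, n in spec:
        for j in range(n):
            image_id = f"{label}_{j:04d}"
            vg = (vessel_groups or {}).get(image_id, f"vg_{image_id}")
            records.append(
                ImageRecord(
                    image_id=image_id,
                    path=f"{image_id}.png",
                    mouse_id=f"m{i % 23:02d}",
                    age_label=label,
                    sex="F" if i % 2 == 0 else "M",
                    region=("CC", "HC", "PFC")[i % 3],
                    vessel_group=vg,
                )
            )
            i += 1
    return DatasetManifest(records)


@pytest.fixture(scope="session")
def study_manifest() -> DatasetManifest:
    """A manifest with the study's class structure: 161 aged, 198 young."""
    return make_records(161, 198)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small rendered synthetic cohort with duplicates and unlabelled images."""
    out = tmp_path_factory.mktemp("small_cohort")
    cfg = SynthConfig(
        n_per_class=12,
        effect_size=3.0,
        duplicate_fraction=0.125,
        n_unlabelled=6,
        seed=11,
    )
    manifest, truths = generate_dataset(cfg, out)
    return {"manifest": manifest, "truths": truths, "dir": out, "cfg": cfg}


@pytest.fixture(scope="session")
def trained_tiny(small_cohort):
    """A tiny-backbone model trained briefly on the small cohort."""
    cfg = PipelineConfig(seed=5)
    labelled = small_cohort["manifest"].labelled()
    cache: dict = {}
    items = prepare_items(labelled, cfg, cache)
    augset = augment_training_set(
        items, cfg, seed=5, ids=[r.image_id for r in labelled.records]
    )
    model = build_model(BackboneSpec("tiny_test"), head=HeadConfig(), seed=5)
    train_head(
        model,
        augset,
        TrainConfig(epochs=4, batch_size=16, learning_rate=1e-3, seed=5),
    )
    return {
        "model": model,
        "items": items,
        "manifest": labelled,
        "cache": cache,
        "pipeline_cfg": cfg,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
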