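"""Manifest-driven dataset handling.

A study dataset is described by a CSV manifest with one row per electron
microscopy image: identifiers, file path, mouse of origin, age-group label,
sex, brain region and a *vessel group* tag marking images that show the same
vessel (at different magnification, position or contrast).  The functions
here load and validate that manifest, one-hot encode the categorical
metadata, perform the age-stratified 90:10 train/test split, guard the test
set against vessel-level leakage, and build stratified cross-validation
folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

AGE_LABELS = ("aged", "young", "unlabelled")
SEXES = ("F", "M")
REGIONS = ("CC", "HC", "PFC")

#: Fixed one-hot layout (alphabetical within each field) so that saved models
#: remain portable across manifests.
METADATA_LAYOUT = ("sex_F", "sex_M", "region_CC", "region_HC", "region_PFC")

MANIFEST_COLUMNS = (
    "image_id",
    "path",
    "mouse_id",
    "age_label",
    "sex",
    "region",
    "vessel_group",
)


class ManifestSchemaError(ValueError):
    """Manifest file is missing a required column."""


class ManifestValidationError(ValueError):
    """A manifest row violates the schema (bad enum, duplicate id, ...)."""


@dataclass(frozen=True)
class ImageRecord:
    """One EM image plus its metadata."""

    image_id: str
    path: Path
    mouse_id: str
    age_label: str  # aged | young | unlabelled
    sex: str  # F | M
    region: str  # CC | HC | PFC
    vessel_group: str
    age_days: int | None = None

    def __post_init__(self) -> None:
        if self.age_label not in AGE_LABELS:
            raise ManifestValidationError(
                f"record {self.image_id!r}: unknown age_label {self.age_label!r}"
            )
        if self.sex not in SEXES:
            raise ManifestValidationError(
                f"record {self.image_id!r}: unknown sex {self.sex!r}"
            )
        if self.region not in REGIONS:
            raise ManifestValidationError(
                f"record {self.image_id!r}: unknown region {self.region!r}"
            )
        if not self.vessel_group:
            raise ManifestValidationError(
                f"record {self.image_id!r}: vessel_group must be non-empty"
            )

    @property
    def is_labelled(self) -> bool:
        return self.age_label != "unlabelled"


@dataclass
class DatasetManifest:
    """An ordered collection of :class:`ImageRecord`."""

    records: list[ImageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestValidationError(f"duplicate image_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {"aged": 0, "young": 0}
        for r in self.records:
            if r.age_label in counts:
                counts[r.age_label] += 1
        return counts

    def labelled(self) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.is_labelled])

    def unlabelled(self) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if not r.is_labelled])

    def subset(self, indices: Iterable[int]) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "path": [str(r.path) for r in self.records],
                "mouse_id": [r.mouse_id for r in self.records],
                "age_label": [r.age_label for r in self.records],
                "sex": [r.sex for r in self.records],
                "region": [r.region for r in self.records],
                "vessel_group": [r.vessel_group for r in self.records],
                "age_days": [r.age_days for r in self.records],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """The fixed constants of the analysis pipeline.

    ``input_size`` (px) and ``pixel_range`` are dictated by the pretrained
    backbones; ``train_fraction`` is the 90:10 age-stratified split;
    ``augmentation_factor`` is the eight-fold dihedral expansion of the
    training data; ``model_selection_folds`` / ``threshold_folds`` are the
    cross-validation depths used for backbone selection and stratification
    threshold optimisation respectively.
    """

    input_size: int = 224
    pixel_range: tuple[float, float] = (-1.0, 1.0)
    train_fraction: float = 0.9
    augmentation_factor: int = 8
    model_selection_folds: int = 10
    threshold_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.augmentation_factor != 8:
            raise ValueError("augmentation_factor is fixed at 8 by the scheme")
        if self.input_size != 224:
            raise ValueError("input_size is fixed at 224 by the backbones")


def subseed(seed: int, tag: str) -> int:
    """Derive a deterministic sub-seed from a global seed and a stage tag.

    A single user-facing seed fans out to independent streams for the split,
    fold shuffling, augmentation order, weight init, etc.
    """
    import zlib

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def load_manifest(manifest_path: str | Path, check_paths: bool = True) -> DatasetManifest:
    """Read a manifest CSV into a validated :class:`DatasetManifest`.

    Raises :class:`ManifestSchemaError` for missing columns and
    :class:`ManifestValidationError` (citing the 1-based data row) for bad
    enum values, duplicate ids or missing image files.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestSchemaError(f"manifest is missing required column {col!r}")

    records: list[ImageRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        image_id = row.image_id
        if image_id in seen:
            raise ManifestValidationError(
                f"row {rownum}: duplicate image_id {image_id!r}"
            )
        seen.add(image_id)
        age_days = None
        if "age_days" in df.columns:
            raw = getattr(row, "age_days", "")
            if raw not in ("", "NA", "nan"):
                age_days = int(float(raw))
        path = Path(row.path)
        if not path.is_absolute():
            # resolve against the manifest's directory so derived manifests
            # saved elsewhere keep pointing at the same image files
            path = (manifest_path.parent / path).resolve()
        if check_paths and not path.exists():
            raise ManifestValidationError(
                f"row {rownum}: image file not found: {path}"
            )
        try:
            rec = ImageRecord(
                image_id=image_id,
                path=path,
                mouse_id=row.mouse_id,
                age_label=row.age_label,
                sex=row.sex,
                region=row.region,
                vessel_group=row.vessel_group,
                age_days=age_days,
            )
        except ManifestValidationError as exc:
            raise ManifestValidationError(f"row {rownum}: {exc}") from None
        records.append(rec)
    manifest = DatasetManifest(records)
    logger.info(
        "loaded manifest %s: %d records, class counts %s",
        manifest_path,
        len(manifest),
        manifest.class_counts,
    )
    return manifest


def encode_metadata(record: ImageRecord) -> np.ndarray:
    """One-hot encode (sex, region) into the fixed 5-long layout.

    Layout: ``[sex_F, sex_M, region_CC, region_HC, region_PFC]``.  One-hot
    encoding (rather than ordinal codes) avoids imposing a spurious order on
    the categories.
    """
    vec = np.zeros(len(METADATA_LAYOUT), dtype=np.float32)
    vec[SEXES.index(record.sex)] = 1.0
    vec[2 + REGIONS.index(record.region)] = 1.0
    return vec


def _per_class_train_count(n: int, fraction: float) -> int:
    # Ceiling allocation: with 161/198 and fraction 0.9 this yields the
    # published 145 + 179 = 324 training / 16 + 19 = 35 test images.
    return math.ceil(fraction * n)


def stratified_split(
    manifest: DatasetManifest, train_fraction: float, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Age-stratified random split of the labelled records.

    Each class is shuffled independently and the first
    ``ceil(train_fraction * class_n)`` records go to the training side.
    Unlabelled records are excluded (they are never used for supervised
    training).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labelled = manifest.labelled()
    by_class: dict[str, list[int]] = {"aged": [], "young": []}
    for i, r in enumerate(labelled.records):
        by_class[r.age_label].append(i)
    for cls, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"cannot stratify: class {cls!r} has {len(idx)} record(s)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in ("aged", "young"):
        idx = np.asarray(by_class[cls])
        perm = rng.permutation(len(idx))
        n_train = _per_class_train_count(len(idx), train_fraction)
        if n_train >= len(idx):
            raise ValueError(
                f"train_fraction {train_fraction} leaves no test records for class {cls!r}"
            )
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train = labelled.subset(sorted(train_idx))
    test = labelled.subset(sorted(test_idx))
    return train, test


def drop_leaky_test_images(
    train: DatasetManifest, test: DatasetManifest
) -> DatasetManifest:
    """Remove test records whose vessel also appears in the training set.

    Images of the same vessel taken at different magnification or position
    would otherwise leak training content into the evaluation.
    """
    train_groups = {r.vessel_group for r in train.records}
    kept = [r for r in test.records if r.vessel_group not in train_groups]
    n_dropped = len(test.records) - len(kept)
    if n_dropped:
        logger.info("dropped %d leaky test image(s)", n_dropped)
    if not kept and test.records:
        logger.warning("all test records shared a vessel with training data")
    return DatasetManifest(kept)


def make_cv_folds(
    train: DatasetManifest, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled, age-stratified k-fold partition of the training manifest.

    Returns ``(fit_idx, val_idx)`` index pairs into ``train.records``; the
    validation sets partition the data and each fold's class balance is
    within one record of the global balance.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.array([r.age_label for r in train.records])
    counts = train.class_counts
    min_class = min(v for v in counts.values())
    if k > min_class:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({min_class}); cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    return [
        (np.asarray(fit), np.asarray(val))
        for fit, val in skf.split(np.zeros(len(labels)), labels)
    ]
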