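"""Eight-fold dihedral augmentation of training folds.

The training data is expanded by the eight symmetries of the square (the
dihedral group D4): identity, rotations by 90/180/270 degrees, horizontal
flip, and the flip composed with each rotation.  On square images every
transform is an exact pixel permutation, so augmentation is lossless: the
multiset of pixel values of each augmented image equals that of its source.
Augmentation is applied only to the fit portion of a split, never to
validation or test data; provenance records make that auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core_data import PipelineConfig

Transform = Callable[[np.ndarray], np.ndarray]


def _rot(k: int) -> Transform:
    return lambda a: np.ascontiguousarray(np.rot90(a, k, axes=(0, 1)))


def _hflip(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.flip(a, axis=1))


#: The 8 elements of D4 in a fixed order. ``hflip_rot90`` means "rotate by
#: 90 degrees, then flip horizontally".
TRANSFORM_ORDER = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "hflip",
    "hflip_rot90",
    "hflip_rot180",
    "hflip_rot270",
)


def dihedral_transforms() -> list[tuple[str, Transform]]:
    """Return the 8 named symmetries of the square, in fixed order."""
    rots = {0: _rot(0), 1: _rot(1), 2: _rot(2), 3: _rot(3)}
    out: list[tuple[str, Transform]] = [
        ("identity", rots[0]),
        ("rot90", rots[1]),
        ("rot180", rots[2]),
        ("rot270", rots[3]),
        ("hflip", _hflip),
    ]
    for k in (1, 2, 3):
        rot = rots[k]
        out.append((f"hflip_rot{90 * k}", lambda a, _rotf=rot: _hflip(_rotf(a))))
    return out


@dataclass(frozen=True)
class AugmentedItem:
    """Provenance of one augmented training item."""

    source_index: int
    source_id: str
    transform: str
    label: int  # 1 = aged, 0 = young


class AugmentedSet:
    """Lazily materialised 8x dihedral expansion of a training set.

    Items are ``(image, metadata, label)`` triples; pixels are computed on
    access so the expansion costs no extra memory beyond the source images.
    ``provenance`` lists, per item, the source image id and transform name.
    """

    def __init__(
        self,
        images: Sequence[np.ndarray],
        metadata: Sequence[np.ndarray],
        labels: Sequence[int],
        ids: Sequence[str],
        order: Sequence[AugmentedItem],
    ) -> None:
        self._images = list(images)
        self._metadata = list(metadata)
        self._labels = list(labels)
        self._ids = list(ids)
        self._order = list(order)
        self._transforms = dict(dihedral_transforms())

    def __len__(self) -> int:
        return len(self._order)

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray, int]:
        item = self._order[i]
        img = self._transforms[item.transform](self._images[item.source_index])
        return img, self._metadata[item.source_index], item.label

    @property
    def provenance(self) -> list[tuple[str, str]]:
        return [(it.source_id, it.transform) for it in self._order]

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self._order], dtype=np.int64)

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {1: int((labels == 1).sum()), 0: int((labels == 0).sum())}

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        """Yield (images NHWC, metadata, labels) batches, optionally shuffled."""
        n = len(self)
        idx = np.arange(n) if rng is None else rng.permutation(n)
        for start in range(0, n, batch_size):
            chunk = idx[start : start + batch_size]
            imgs, metas, labels = zip(*(self[int(i)] for i in chunk))
            yield (
                np.stack(imgs).astype(np.float32),
                np.stack(metas).astype(np.float32),
                np.asarray(labels, dtype=np.float32),
            )


def augment_training_set(
    source: Sequence[tuple[np.ndarray, np.ndarray, int]],
    cfg: PipelineConfig,
    seed: int,
    ids: Sequence[str] | None = None,
) -> AugmentedSet:
    """Expand a training set 8-fold with the dihedral transforms.

    The result is the concatenation of the source under each of the eight
    transforms, shuffled with ``seed``.  Labels and metadata are inherited
    from the source item.  Images must be square (the transforms are then
    exact pixel permutations).
    """
    if cfg.augmentation_factor != 8:
        raise ValueError("augmentation_factor is fixed at 8 by the scheme")
    images = [np.asarray(img) for img, _meta, _label in source]
    for img in images:
        if img.shape[0] != img.shape[1]:
            raise ValueError("augmentation requires square model images")
    metadata = [meta for _img, meta, _label in source]
    labels = [int(label) for _img, _meta, label in source]
    ids = list(ids) if ids is not None else [f"item{i}" for i in range(len(source))]
    if len(ids) != len(source):
        raise ValueError("ids must match source length")
    order = [
        AugmentedItem(i, ids[i], tname, labels[i])
        for tname in TRANSFORM_ORDER
        for i in range(len(source))
    ]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(order))
    order = [order[int(p)] for p in perm]
    return AugmentedSet(images, metadata, labels, ids, order)


def materialize(
    augset: AugmentedSet, out_dir: str | Path, prefix: str = "aug"
) -> Path:
    """Write the augmented set to PNGs plus a provenance CSV (offline mode)."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(augset)):
        img, _meta, label = augset[i]
        src, tname = augset.provenance[i]
        u8 = np.clip((img + 1.0) * 127.5, 0, 255).astype(np.uint8)
        fname = f"{prefix}_{i:05d}.png"
        iio.imwrite(out_dir / fname, u8)
        rows.append(
            {"file": fname, "source_id": src, "transform": tname, "label": label}
        )
    csv_path = out_dir / f"{prefix}_provenance.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
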