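"""Seeded generator of synthetic capillary-cross-section images.

Each image emulates the content of a transmission-EM field of view centred
on a brain capillary: a bright lumen ellipse, a darker vessel-wall annulus
(endothelium plus basement membrane), perivascular blobs abutting the wall
(the analogue of astrocyte endfeet), and multiplicative speckle texture
over the surrounding parenchyma.  The class effect is localised to the wall:
aged vessels have a thicker annulus (mean shifted by ``effect_size``
standard deviations of the thickness noise) and a higher perivascular blob
rate, mirroring the basement-membrane thickening and endfoot swelling
reported for the ageing blood-brain barrier.  Ground-truth geometry is
recorded per image so that localisation claims (e.g. Grad-CAM mass inside
the wall region) can be scored exactly.

Every image is a pure function of (seed, image index), so datasets are
bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_data import REGIONS, DatasetManifest, load_manifest

# rendering intensity levels (uint8 scale)
_LUMEN_VAL = 230.0
_WALL_VAL = 60.0
_BLOB_VAL = 110.0
_PARENCHYMA_VAL = 150.0


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    ``effect_size`` is the standardised shift in wall thickness between
    classes: aged mean thickness = young mean + effect_size * ring_noise_sd.
    ``endfoot_blob_rate_aged`` is the Poisson mean of perivascular blobs for
    aged vessels; young vessels use half that rate.  ``duplicate_fraction``
    of the images are second acquisitions of an already-rendered vessel
    (same vessel_group, different magnification and noise), exercising the
    leakage guard downstream.
    """

    n_per_class: int = 150
    image_size: int = 512
    effect_size: float = 3.0
    ring_thickness_mean_young: float = 30.0
    ring_noise_sd: float = 6.0
    texture_grain: float = 3.0
    lumen_radius_range: tuple[float, float] = (55.0, 85.0)
    endfoot_blob_rate_aged: float = 6.0
    duplicate_fraction: float = 0.05
    n_unlabelled: int = 0
    region_confound: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.duplicate_fraction < 0.5:
            raise ValueError("duplicate_fraction must lie in [0, 0.5)")

    def thickness_mean(self, age_class: str) -> float:
        if age_class == "aged":
            return self.ring_thickness_mean_young + self.effect_size * self.ring_noise_sd
        if age_class == "young":
            return self.ring_thickness_mean_young
        # unlabelled cohort: halfway between the two classes
        return self.ring_thickness_mean_young + 0.5 * self.effect_size * self.ring_noise_sd

    def blob_rate(self, age_class: str) -> float:
        if age_class == "aged":
            return self.endfoot_blob_rate_aged
        if age_class == "young":
            return 0.5 * self.endfoot_blob_rate_aged
        return 0.75 * self.endfoot_blob_rate_aged


@dataclass
class GroundTruth:
    """Rendered geometry and metadata of one synthetic image."""

    image_id: str
    age_class: str
    center: tuple[float, float]  # (row, col)
    axis_a: float  # semi-axis along columns, px
    axis_b: float  # semi-axis along rows, px
    inner_radius: float  # mean lumen radius, px
    outer_radius: float  # inner_radius + wall thickness, px
    thickness: float
    blob_centers: list[tuple[float, float]]
    blob_radius: float
    magnification: float
    organelles: list[tuple[float, float, float, float]] = field(default_factory=list)
    sex: str = "F"
    region: str = "CC"
    mouse_id: str = ""
    vessel_group: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _soft_mask(rho: np.ndarray, edge: float, softness: float) -> np.ndarray:
    """Soft indicator of rho <= edge with ~``softness`` wide transition."""
    return np.clip((edge - rho) / softness + 0.5, 0.0, 1.0)


def generate_image(
    age_class: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    magnification: float = 1.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic capillary image; deterministic in ``rng`` state.

    Returns a uint8 grayscale array of shape (image_size, image_size) and
    the ground-truth geometry.  Vessel geometry that would exceed the image
    bounds is resampled; after 100 attempts an error is raised.
    """
    size = cfg.image_size
    mean_t = cfg.thickness_mean(age_class)
    for _attempt in range(100):
        cy = size / 2 + rng.uniform(-0.06, 0.06) * size
        cx = size / 2 + rng.uniform(-0.06, 0.06) * size
        r0 = rng.uniform(*cfg.lumen_radius_range) * magnification
        ecc = rng.uniform(0.0, 0.06)
        a, b = r0 * (1 + ecc), r0 * (1 - ecc)
        thickness = rng.normal(mean_t, cfg.ring_noise_sd) * magnification
        thickness = max(thickness, 4.0)
        blob_margin = 30.0 * magnification
        extent = max(a, b) + thickness + blob_margin
        if extent < min(cy, cx, size - cy, size - cx):
            break
    else:
        raise RuntimeError("could not place vessel geometry inside image bounds")

    r_eff = 0.5 * (a + b)
    rho_out = 1.0 + thickness / r_eff

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rho = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)

    # multiplicative speckle over the parenchyma
    noise = gaussian_filter(rng.standard_normal((size, size)), cfg.texture_grain)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    parenchyma = _PARENCHYMA_VAL * np.exp(0.12 * noise)

    # the wall carries its own finer-grained, higher-contrast texture
    # (endothelial cytoplasm and basement membrane are organelle-rich in EM);
    # rendering it as a flat dark band would leave the annulus without
    # positive structure for a feature extractor to respond to
    wall_noise = gaussian_filter(rng.standard_normal((size, size)), 2.5)
    sd = wall_noise.std()
    if sd > 0:
        wall_noise /= sd
    wall_tex = _WALL_VAL * np.exp(0.15 * wall_noise)

    soft = 2.0 / r_eff  # ~2 px transition expressed in normalised radius
    w_lumen = _soft_mask(rho, 1.0, soft)
    w_wall = np.clip(_soft_mask(rho, rho_out, soft) - w_lumen, 0.0, 1.0)
    img = w_lumen * _LUMEN_VAL + w_wall * wall_tex + (1 - w_lumen - w_wall) * parenchyma

    # class-independent dark organelle-like bodies (nuclei, mitochondria,
    # myelin profiles) scattered through the parenchyma: their variable total
    # dark area dominates the per-image histogram, so global-intensity
    # statistics (e.g. after histogram equalisation) carry no usable class
    # signal and the discriminative information stays localised to the wall
    n_org = int(rng.poisson(6.0))
    organelles: list[tuple[float, float, float, float]] = []
    for _ in range(n_org):
        oy = rng.uniform(10.0, size - 10.0)
        ox = rng.uniform(10.0, size - 10.0)
        oa = rng.uniform(25.0, 65.0)
        ob = rng.uniform(25.0, 65.0)
        level = rng.uniform(45.0, 95.0)
        ro = np.sqrt(((xx - ox) / oa) ** 2 + ((yy - oy) / ob) ** 2)
        wo = _soft_mask(ro, 1.0, 4.0 / (oa + ob))
        wo = wo * (1 - w_lumen - w_wall)  # never overwrite lumen or wall
        img = wo * level + (1 - wo) * img
        organelles.append((oy, ox, oa, ob))

    # perivascular blobs hugging the outer wall boundary
    n_blobs = int(rng.poisson(cfg.blob_rate(age_class)))
    blob_radius = 12.0 * magnification
    outer_px = r_eff + thickness
    blob_centers: list[tuple[float, float]] = []
    for _ in range(n_blobs):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dist = outer_px + blob_radius * rng.uniform(0.4, 1.2)
        by = cy + dist * math.sin(theta)
        bx = cx + dist * math.cos(theta)
        if not (0 <= by < size and 0 <= bx < size):
            continue
        br = blob_radius * rng.uniform(0.7, 1.3)
        rb = np.sqrt((xx - bx) ** 2 + (yy - by) ** 2) / br
        wb = _soft_mask(rb, 1.0, 2.0 / br)
        wb = wb * (1 - w_lumen - w_wall)  # blobs never overwrite lumen or wall
        img = wb * _BLOB_VAL + (1 - wb) * img
        blob_centers.append((by, bx))

    img = img + rng.normal(0.0, 4.0, (size, size))
    img = np.clip(img, 0, 255).astype(np.uint8)

    gt = GroundTruth(
        image_id="",
        age_class=age_class,
        center=(cy, cx),
        axis_a=a,
        axis_b=b,
        inner_radius=r_eff,
        outer_radius=outer_px,
        thickness=thickness,
        blob_centers=blob_centers,
        blob_radius=blob_radius,
        magnification=magnification,
        organelles=organelles,
    )
    return img, gt


def _assign_metadata(
    age_class: str, index: int, n_mice: int, rng: np.random.Generator, cfg: SynthConfig
) -> tuple[str, str, str]:
    """(mouse_id, sex, region): balanced and class-independent by default."""
    mouse_idx = index % n_mice
    mouse_id = f"{age_class}_m{mouse_idx:02d}"
    sex = "F" if mouse_idx % 2 == 0 else "M"
    region = REGIONS[index % len(REGIONS)]
    if cfg.region_confound > 0 and rng.random() < cfg.region_confound:
        region = "CC" if age_class == "aged" else "PFC"
    return mouse_id, sex, region


def generate_dataset(
    cfg: SynthConfig, out_dir: str | Path
) -> tuple[DatasetManifest, dict[str, GroundTruth]]:
    """Render a full synthetic cohort to ``out_dir``.

    Writes PNG images, a ``manifest.csv`` loadable by
    :func:`vesselage.core_data.load_manifest`, and a ``groundtruth.json``
    sidecar.  Sexes and brain regions are balanced within each class and
    assigned independently of class (no confound) unless
    ``region_confound`` is set.  A ``duplicate_fraction`` of the images are
    re-acquisitions of an existing vessel at higher magnification, sharing
    its ``vessel_group``.
    """
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    truths: dict[str, GroundTruth] = {}
    n_dupes_total = int(round(cfg.duplicate_fraction * 2 * cfg.n_per_class))
    dupes_per_class = {
        "aged": n_dupes_total // 2 + (n_dupes_total % 2),
        "young": n_dupes_total // 2,
    }

    counter = 0
    for age_class in ("aged", "young"):
        n_dupes = min(dupes_per_class[age_class], cfg.n_per_class // 2)
        n_unique = cfg.n_per_class - n_dupes
        n_mice = max(3, n_unique // 13)
        primaries: list[tuple[str, GroundTruth]] = []
        for i in range(n_unique):
            rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, counter])
            img, gt = generate_image(age_class, cfg, rng)
            image_id = f"{age_class}_{i:04d}"
            mouse_id, sex, region = _assign_metadata(age_class, i, n_mice, rng, cfg)
            gt.image_id, gt.mouse_id, gt.sex, gt.region = image_id, mouse_id, sex, region
            gt.vessel_group = f"vessel_{age_class}_{i:04d}"
            fname = f"{image_id}.png"
            iio.imwrite(out_dir / fname, img)
            truths[image_id] = gt
            rows.append(
                {
                    "image_id": image_id,
                    "path": fname,
                    "mouse_id": mouse_id,
                    "age_label": age_class,
                    "sex": sex,
                    "region": region,
                    "vessel_group": gt.vessel_group,
                    "age_days": {"aged": 577, "young": 98}.get(age_class, ""),
                }
            )
            primaries.append((image_id, gt))
            counter += 1
        # re-acquisitions of existing vessels at higher magnification
        for d in range(n_dupes):
            src_id, src_gt = primaries[d]
            rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, counter])
            img, gt = generate_image(age_class, cfg, rng, magnification=1.2)
            image_id = f"{age_class}_dup{d:03d}"
            gt.image_id = image_id
            gt.mouse_id, gt.sex, gt.region = src_gt.mouse_id, src_gt.sex, src_gt.region
            gt.vessel_group = src_gt.vessel_group
            fname = f"{image_id}.png"
            iio.imwrite(out_dir / fname, img)
            truths[image_id] = gt
            rows.append(
                {
                    "image_id": image_id,
                    "path": fname,
                    "mouse_id": gt.mouse_id,
                    "age_label": age_class,
                    "sex": gt.sex,
                    "region": gt.region,
                    "vessel_group": gt.vessel_group,
                    "age_days": {"aged": 577, "young": 98}.get(age_class, ""),
                }
            )
            counter += 1

    # optional unlabelled (middle-age analogue) cohort: CC and PFC only
    n_mice_unl = 3
    for i in range(cfg.n_unlabelled):
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, counter])
        img, gt = generate_image("unlabelled", cfg, rng)
        image_id = f"unlabelled_{i:04d}"
        gt.image_id = image_id
        gt.mouse_id = f"middle_m{i % n_mice_unl:02d}"
        gt.sex = "F"
        gt.region = "CC" if i % 2 == 0 else "PFC"
        gt.vessel_group = f"vessel_unl_{i:04d}"
        fname = f"{image_id}.png"
        iio.imwrite(out_dir / fname, img)
        truths[image_id] = gt
        rows.append(
            {
                "image_id": image_id,
                "path": fname,
                "mouse_id": gt.mouse_id,
                "age_label": "unlabelled",
                "sex": gt.sex,
                "region": gt.region,
                "vessel_group": gt.vessel_group,
                "age_days": 366,
            }
        )
        counter += 1

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    (out_dir / "groundtruth.json").write_text(
        json.dumps({k: v.to_dict() for k, v in truths.items()}, indent=1)
    )
    manifest = load_manifest(manifest_path)
    return manifest, truths


def load_groundtruth(path: str | Path) -> dict[str, GroundTruth]:
    data = json.loads(Path(path).read_text())
    out = {}
    for k, d in data.items():
        d["center"] = tuple(d["center"])
        d["blob_centers"] = [tuple(c) for c in d["blob_centers"]]
        d["organelles"] = [tuple(o) for o in d.get("organelles", [])]
        out[k] = GroundTruth(**d)
    return out


def ring_mask(
    gt: GroundTruth, image_size: int, out_size: int = 224, dilation: float = 1.5
) -> np.ndarray:
    """Boolean mask of the (dilated) wall annulus in the resized frame.

    The annulus between ``inner_radius / dilation`` and
    ``outer_radius * dilation`` (elliptical, following the rendered axes)
    is rescaled from the rendering frame to ``out_size``.
    """
    scale = out_size / image_size
    cy, cx = gt.center[0] * scale, gt.center[1] * scale
    a, b = gt.axis_a * scale, gt.axis_b * scale
    yy, xx = np.mgrid[0:out_size, 0:out_size].astype(np.float64)
    rho = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    r_eff = 0.5 * (a + b)
    inner = (gt.inner_radius * scale / dilation) / r_eff
    outer = (gt.outer_radius * scale * dilation) / r_eff
    return (rho >= inner) & (rho <= outer)


def recover_ring_radii(
    img: np.ndarray, gt: GroundTruth, n_bins: int = 120
) -> tuple[float, float]:
    """Estimate (inner, outer) wall radii by radial intensity profiling.

    Sanity oracle for the renderer: bins pixels by normalised elliptical
    radius around the known centre/axes, finds the dark band containing the
    profile minimum, and returns its radial extent in pixels.
    """
    size = img.shape[0]
    cy, cx = gt.center
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rho = np.sqrt(((xx - cx) / gt.axis_a) ** 2 + ((yy - cy) / gt.axis_b) ** 2)
    r_eff = 0.5 * (gt.axis_a + gt.axis_b)
    rmax = 2.5
    edges = np.linspace(0.0, rmax, n_bins + 1)
    idx = np.clip(np.digitize(rho.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=img.ravel().astype(np.float64), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = sums / np.maximum(counts, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    threshold = 0.5 * (_WALL_VAL + _PARENCHYMA_VAL)
    lo = hi = int(np.argmin(profile))
    while lo > 0 and profile[lo - 1] < threshold:
        lo -= 1
    while hi < n_bins - 1 and profile[hi + 1] < threshold:
        hi += 1
    return centers[lo] * r_eff, centers[hi] * r_eff
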