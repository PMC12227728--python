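"""Fixed image-preprocessing chain producing model-ready arrays.

Raw EM frames (nominally 4096x4096, 8- or 16-bit, grayscale content even
when stored as RGB) pass through, in order: global histogram equalisation on
the luminance, an Otsu-derived soft background floor, downsampling to
224x224, replication to three channels, and an affine rescale to [-1, 1].
The chain is deterministic and resolution-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from skimage import exposure, transform

from .core_data import PipelineConfig

logger = logging.getLogger(__name__)

MODEL_SIZE = 224


def _max_for_dtype(img: np.ndarray) -> float:
    if img.dtype == np.uint8:
        return 255.0
    if img.dtype == np.uint16:
        return 65535.0
    m = float(img.max()) if img.size else 1.0
    return m if m > 1.0 else 1.0


def luminance(img: np.ndarray) -> np.ndarray:
    """Channel-mean luminance of an HxW or HxWx3 image (float64)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        return arr.mean(axis=2)
    return arr


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalisation on the luminance representation.

    The equalised luminance is mapped back onto the input's channel layout
    (EM "RGB" content is effectively single-channel, so the equalised plane
    is replicated rather than equalising per channel, which could introduce
    false colour).  Constant images are returned unchanged.  The mapping is
    the standard CDF transform and therefore preserves pixel rank order.
    """
    arr = np.asarray(img)
    lum = luminance(arr)
    if lum.max() == lum.min():
        return arr.copy()
    maxval = _max_for_dtype(arr)
    eq = exposure.equalize_hist(lum, nbins=256) * maxval
    if np.issubdtype(arr.dtype, np.integer):
        eq = np.floor(eq).astype(arr.dtype)
    else:
        eq = eq.astype(arr.dtype)
    if arr.ndim == 3:
        eq = np.repeat(eq[:, :, None], arr.shape[2], axis=2)
    return eq


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold with a plateau-midpoint tie-break.

    For histograms whose two populations are separated by empty bins, every
    threshold inside the gap maximises the between-class variance; the
    midpoint of that maximising plateau is returned (implementations that
    return the plateau's low edge would place the threshold directly above
    the background mode, defeating a threshold-relative floor).
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(vals, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(np.float64) / hist.sum()
    mu = centers * w
    omega0 = np.cumsum(w)[:-1]
    omega1 = 1.0 - omega0
    mu0 = np.cumsum(mu)[:-1]
    mu_total = mu.sum()
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.zeros(nbins - 1)
    sigma_b[valid] = (mu_total * omega0[valid] - mu0[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    peak = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= peak * (1.0 - 1e-12))
    mid = plateau[len(plateau) // 2]
    return float(edges[mid + 1])


def threshold_denoise(img: np.ndarray, method: str = "otsu_floor", floor_fraction: float = 0.5) -> np.ndarray:
    """Suppress dark background noise with an Otsu-derived soft floor.

    ``otsu_floor`` computes the Otsu threshold ``t`` on the luminance and
    zeroes every pixel whose luminance falls below ``floor_fraction * t``;
    pixels at or above the floor are kept unchanged.  This simplifies the
    background without binarising away the texture the classifier needs.
    ``none`` is the identity.  Never increases any pixel value.
    """
    if method == "none":
        return np.asarray(img).copy()
    if method != "otsu_floor":
        raise ValueError(f"unknown thresholding method {method!r}")
    arr = np.asarray(img).copy()
    lum = luminance(arr)
    if lum.max() == lum.min():
        return arr
    t = otsu_threshold(lum)
    mask = lum < floor_fraction * t
    arr[mask] = 0
    return arr


def resize_to_model(img: np.ndarray, size: int = MODEL_SIZE) -> np.ndarray:
    """Downsample to ``size`` x ``size`` (float64, original intensity scale).

    Non-square inputs are centre-cropped to square first (with a warning).
    When the scale factor is an exact integer the resize is area averaging
    (each output pixel is the mean of its source block); otherwise an
    antialiased bilinear resize is used.
    """
    arr = np.asarray(img, dtype=np.float64)
    h, w = arr.shape[:2]
    if h != w:
        warnings.warn("non-square input; centre-cropping to square before resize")
        side = min(h, w)
        r0 = (h - side) // 2
        c0 = (w - side) // 2
        arr = arr[r0 : r0 + side, c0 : c0 + side]
        h = w = side
    if h == size:
        return arr
    if h % size == 0:
        f = h // size
        factors = (f, f) + (1,) * (arr.ndim - 2)
        return transform.downscale_local_mean(arr, factors)
    out_shape = (size, size) + arr.shape[2:]
    return transform.resize(
        arr, out_shape, order=1, anti_aliasing=h > size, preserve_range=True
    )


def to_model_image(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Apply the full chain: equalise, floor, resize, RGB, scale to [-1, 1].

    Returns a float32 array of shape (224, 224, 3) with values in [-1, 1].
    Single-channel inputs are replicated to three channels; the intensity
    rescale is the affine map of the input's representable range onto the
    configured pixel range (0 -> -1, max -> +1 for unsigned integers).
    """
    cfg = cfg or PipelineConfig()
    arr = np.asarray(img)
    maxval = _max_for_dtype(arr)
    arr = equalize_histogram(arr)
    arr = threshold_denoise(arr)
    arr = resize_to_model(arr, cfg.input_size)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    lo, hi = cfg.pixel_range
    out = lo + (hi - lo) * (arr / maxval)
    return np.clip(out, lo, hi).astype(np.float32)


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG image as a numpy array."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path)))


def write_debug_chain(img: np.ndarray, out_dir: str | Path, stem: str = "img") -> list[Path]:
    """Write each intermediate of the chain as PNG for visual inspection."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = {
        "0_raw": np.asarray(img),
        "1_equalized": equalize_histogram(img),
    }
    stages["2_floored"] = threshold_denoise(stages["1_equalized"])
    resized = resize_to_model(stages["2_floored"])
    maxval = _max_for_dtype(np.asarray(img))
    stages["3_resized"] = np.clip(resized / maxval * 255.0, 0, 255).astype(np.uint8)
    paths = []
    for name, arr in stages.items():
        if arr.dtype == np.uint16:
            arr = (arr / 257).astype(np.uint8)
        elif arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        p = out_dir / f"{stem}_{name}.png"
        iio.imwrite(p, arr)
        paths.append(p)
    return paths
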