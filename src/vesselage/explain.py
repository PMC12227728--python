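"""Grad-CAM spatial relevance maps and overlays.

Gradient-weighted class activation mapping: for a chosen convolutional
layer, each channel's weight is the spatial mean of the gradient of the
target-class logit with respect to that channel's activation map; the raw
relevance map is the positive part of the weighted sum of activation maps.
The raw map is bilinearly upsampled to the 224x224 input frame and
max-normalised to [0, 1] (an all-zero map stays all-zero).

Because the classifier has a single sigmoid output, the aged-class logit is
the network output ``z`` and the young-class logit is ``-z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import transform

from . import nn
from .network import FusionModel

MODEL_SIZE = 224


@dataclass
class GradCAMMap:
    """Per-layer spatial relevance heatmap aligned to the input image."""

    layer_id: str
    raw: np.ndarray  # (h, w), non-negative
    upsampled: np.ndarray  # (224, 224) in [0, 1]
    target_class: str  # aged | young

    def __post_init__(self) -> None:
        if (self.raw < 0).any():
            raise ValueError("raw Grad-CAM map must be non-negative")


def _conv_layers(model: FusionModel) -> list[str]:
    return [
        name
        for name, layer in model.backbone.named_layers()
        if isinstance(layer, nn.Conv2d)
    ]


def gradcam(
    model: FusionModel,
    image: np.ndarray,
    meta: np.ndarray,
    layer_id: str,
    target: str | None = None,
) -> GradCAMMap:
    """Grad-CAM map for one image at a named backbone convolutional layer.

    ``target`` selects the class whose logit is differentiated; ``None``
    uses the model's predicted class for this input.
    """
    conv_names = _conv_layers(model)
    if layer_id not in conv_names:
        raise KeyError(
            f"unknown layer {layer_id!r}; available convolutional layers: {conv_names}"
        )
    layer = model.backbone.find(layer_id)

    logit = model.forward(image[None], np.atleast_2d(meta), train=False)[0]
    if target is None:
        target = "aged" if logit >= 0 else "young"
    if target not in ("aged", "young"):
        raise ValueError(f"target must be 'aged' or 'young', got {target!r}")
    sign = 1.0 if target == "aged" else -1.0

    for p in model.backbone.all_params() + model.head.all_params():
        p.zero_grad()
    model.backward(np.array([sign], dtype=np.float32))

    activations = layer.last_output[0]  # (C, h, w)
    grads = layer.last_output_grad[0]  # (C, h, w)
    weights = grads.mean(axis=(1, 2))  # channel weights
    raw = np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)

    up = transform.resize(
        raw.astype(np.float64), (MODEL_SIZE, MODEL_SIZE), order=1, preserve_range=True
    )
    peak = up.max()
    if peak > 0:
        up = up / peak
    return GradCAMMap(layer_id=layer_id, raw=raw, upsampled=up, target_class=target)


def overlay(
    cam: GradCAMMap, image: np.ndarray, colormap: str = "jet"
) -> np.ndarray:
    """Alpha-blend a warm-to-cool colormap over the grayscale image.

    The per-pixel blend weight is proportional to the normalised map value,
    so an all-zero map returns the base image unchanged and the hottest
    pixel shows the warm end of the colormap.  Returns a (224, 224, 3)
    float array in [0, 1].
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.shape != cam.upsampled.shape:
        raise ValueError(
            f"image shape {arr.shape} does not match map shape {cam.upsampled.shape}"
        )
    lo, hi = arr.min(), arr.max()
    base = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    heat = colormaps[colormap](cam.upsampled)[:, :, :3]
    alpha = 0.5 * cam.upsampled[:, :, None]
    out = (1.0 - alpha) * base[:, :, None] + alpha * heat
    return np.clip(out, 0.0, 1.0)


def layer_panel(
    model: FusionModel,
    image: np.ndarray,
    meta: np.ndarray,
    layer_ids: Sequence[str],
    target: str | None = None,
    colormap: str = "jet",
) -> list[np.ndarray]:
    """One overlay per requested layer, for a consistent target class.

    With ``target=None`` the model's predicted class for this input is used
    for every layer, giving a local-to-contextual comparison across the
    network depth.
    """
    if not layer_ids:
        raise ValueError("need at least one layer id")
    if target is None:
        logit = model.forward(image[None], np.atleast_2d(meta), train=False)[0]
        target = "aged" if logit >= 0 else "young"
    return [
        overlay(gradcam(model, image, meta, lid, target), image, colormap)
        for lid in layer_ids
    ]


def save_panel(
    panels: Sequence[np.ndarray], path: str | Path, titles: Sequence[str] | None = None
) -> None:
    """Write a row of overlays to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3))
    if len(panels) == 1:
        axes = [axes]
    for i, (ax, panel) in enumerate(zip(axes, panels)):
        ax.imshow(panel)
        ax.set_axis_off()
        if titles is not None:
            ax.set_title(titles[i], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
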