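"""Multimodal age-likelihood classifier.

A convolutional backbone turns a 224x224x3 image (pixels in [-1, 1]) into a
feature vector; that vector is concatenated with the 5-long one-hot
demographic/anatomical metadata and passed through a small fully connected
head ending in a sigmoid, yielding the probability that the image comes from
an aged brain.  Backbone layers below a configurable cut point stay frozen
(transfer-learning style); training minimises binary cross-entropy plus an
L2 penalty on the head weights, updating only the unfrozen parameters.

Backbones: ``resnet50``, ``mobilenetv2``, ``vgg16``, ``vgg19`` (standard
architectures built in the in-package engine; ImageNet checkpoints are used
when a weights file is supplied, otherwise random initialisation with a
warning) and ``tiny_test``, a three-block randomly initialised network that
trains in seconds on CPU and carries the synthetic-data experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .augment import AugmentedSet
from .core_data import METADATA_LAYOUT, PipelineConfig

BACKBONE_NAMES = ("resnet50", "mobilenetv2", "vgg16", "vgg19", "tiny_test")


@dataclass(frozen=True)
class BackboneSpec:
    """Which convolutional feature extractor to use and where to cut.

    ``frozen_through`` names the last *frozen* top-level layer; everything
    after it (plus the head) is trainable.  ``None`` selects the
    per-architecture default, which keeps the large early portion frozen.
    """

    name: str = "tiny_test"
    pretrained: bool = False
    frozen_through: str | None = None
    weights_path: str | None = None

    def __post_init__(self) -> None:
        if self.name not in BACKBONE_NAMES:
            raise ValueError(
                f"unknown backbone {self.name!r}; valid names: {BACKBONE_NAMES}"
            )
        if self.name == "tiny_test" and self.pretrained:
            raise ValueError("tiny_test has no pretrained weights")


@dataclass(frozen=True)
class HeadConfig:
    """Fully connected head: hidden ReLU layers, dropout, sigmoid output."""

    hidden_sizes: tuple[int, ...] = (256,)
    dropout: float = 0.2
    l2_lambda: float = 1e-4

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for head fine-tuning."""

    epochs: int = 11
    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class AgePrediction:
    """Per-image age-likelihood score in [0, 1] (probability of 'aged')."""

    image_id: str
    score: float
    true_label: str | None = None  # aged | young | None
    sex: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


# ---------------------------------------------------------------------------
# Backbone architectures
# ---------------------------------------------------------------------------


class Bottleneck(nn.Layer):
    """ResNet bottleneck block: 1x1 -> 3x3 -> 1x1 with a residual skip."""

    def __init__(self, cin: int, planes: int, stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        cout = planes * 4
        self.conv1 = nn.Conv2d(cin, planes, 1, rng=rng, bias=False)
        self.bn1 = nn.BatchNorm2d(planes)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, pad=1, rng=rng, bias=False)
        self.bn2 = nn.BatchNorm2d(planes)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(planes, cout, 1, rng=rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        self.downsample: nn.Sequential | None = None
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                [
                    ("conv", nn.Conv2d(cin, cout, 1, stride=stride, rng=rng, bias=False)),
                    ("bn", nn.BatchNorm2d(cout)),
                ]
            )
        self.relu_out = nn.ReLU()

    def sublayers(self) -> list[tuple[str, nn.Layer]]:
        subs = [
            ("conv1", self.conv1), ("bn1", self.bn1), ("relu1", self.relu1),
            ("conv2", self.conv2), ("bn2", self.bn2), ("relu2", self.relu2),
            ("conv3", self.conv3), ("bn3", self.bn3),
        ]
        if self.downsample is not None:
            subs.append(("downsample", self.downsample))
        subs.append(("relu_out", self.relu_out))
        return subs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        m = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        m = self.relu2.forward(self.bn2.forward(self.conv2.forward(m, train), train), train)
        m = self.bn3.forward(self.conv3.forward(m, train), train)
        s = self.downsample.forward(x, train) if self.downsample is not None else x
        out = self.relu_out.forward(m + s, train)
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        g = self.relu_out.backward(gy)
        gm = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(self.relu2.backward(
                    self.conv3.backward(self.bn3.backward(g))
                )))
            ))
        )
        gs = self.downsample.backward(g) if self.downsample is not None else g
        return gm + gs


class InvertedResidual(nn.Layer):
    """MobileNetV2 inverted residual: expand 1x1, depthwise 3x3, project 1x1."""

    def __init__(self, cin: int, cout: int, stride: int, expand: int, rng: np.random.Generator) -> None:
        super().__init__()
        mid = cin * expand
        self.use_skip = stride == 1 and cin == cout
        self.expand_conv: nn.Conv2d | None = None
        if expand != 1:
            self.expand_conv = nn.Conv2d(cin, mid, 1, rng=rng, bias=False)
            self.expand_bn = nn.BatchNorm2d(mid)
            self.expand_relu = nn.ReLU6()
        self.dw_conv = nn.Conv2d(mid, mid, 3, stride=stride, pad=1, groups=mid, rng=rng, bias=False)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.dw_relu = nn.ReLU6()
        self.project_conv = nn.Conv2d(mid, cout, 1, rng=rng, bias=False)
        self.project_bn = nn.BatchNorm2d(cout)

    def sublayers(self) -> list[tuple[str, nn.Layer]]:
        subs: list[tuple[str, nn.Layer]] = []
        if self.expand_conv is not None:
            subs += [("expand_conv", self.expand_conv), ("expand_bn", self.expand_bn),
                     ("expand_relu", self.expand_relu)]
        subs += [("dw_conv", self.dw_conv), ("dw_bn", self.dw_bn), ("dw_relu", self.dw_relu),
                 ("project_conv", self.project_conv), ("project_bn", self.project_bn)]
        return subs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        if self.expand_conv is not None:
            h = self.expand_relu.forward(self.expand_bn.forward(self.expand_conv.forward(h, train), train), train)
        h = self.dw_relu.forward(self.dw_bn.forward(self.dw_conv.forward(h, train), train), train)
        h = self.project_bn.forward(self.project_conv.forward(h, train), train)
        out = h + x if self.use_skip else h
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        g = self.dw_conv.backward(self.dw_bn.backward(self.dw_relu.backward(
            self.project_conv.backward(self.project_bn.backward(gy))
        )))
        if self.expand_conv is not None:
            g = self.expand_conv.backward(self.expand_bn.backward(self.expand_relu.backward(g)))
        return g + gy if self.use_skip else g


def _build_tiny(rng: np.random.Generator) -> tuple[nn.Sequential, int, str]:
    # the final conv layer runs at 1/8 of the input side (28x28 for a 224
    # input): coarser maps cannot resolve the few-pixel structural
    # differences the classifier must read
    layers: list[tuple[str, nn.Layer]] = [
        ("stem", nn.AvgPool2d(2)),
        ("conv1", nn.Conv2d(3, 8, 3, stride=2, pad=1, rng=rng)),
        ("relu1", nn.ReLU()),
        ("pool1", nn.MaxPool2d()),
        ("conv2", nn.Conv2d(8, 16, 3, pad=1, rng=rng)),
        ("relu2", nn.ReLU()),
        ("conv3", nn.Conv2d(16, 32, 3, pad=1, rng=rng)),
        ("relu3", nn.ReLU()),
        ("gap", nn.GlobalAvgPool()),
    ]
    # both learnable conv blocks stay trainable: the backbone is randomly
    # initialised, so there is no pretrained representation worth freezing,
    # and a frozen random conv2 caps what the final block can express
    return nn.Sequential(layers), 32, "pool1"


def _build_vgg(cfg: Sequence[int | str], rng: np.random.Generator) -> tuple[nn.Sequential, int, str]:
    layers: list[tuple[str, nn.Layer]] = []
    cin, block, conv_i = 3, 1, 1
    last_frozen = ""
    for item in cfg:
        if item == "M":
            layers.append((f"block{block}_pool", nn.MaxPool2d()))
            if block == 4:
                last_frozen = f"block{block}_pool"
            block, conv_i = block + 1, 1
        else:
            cout = int(item)
            layers.append((f"block{block}_conv{conv_i}", nn.Conv2d(cin, cout, 3, pad=1, rng=rng)))
            layers.append((f"block{block}_relu{conv_i}", nn.ReLU()))
            cin, conv_i = cout, conv_i + 1
    layers.append(("gap", nn.GlobalAvgPool()))
    return nn.Sequential(layers), cin, last_frozen


_VGG16 = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]
_VGG19 = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M", 512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


def _build_resnet50(rng: np.random.Generator) -> tuple[nn.Sequential, int, str]:
    layers: list[tuple[str, nn.Layer]] = [
        ("stem_conv", nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng, bias=False)),
        ("stem_bn", nn.BatchNorm2d(64)),
        ("stem_relu", nn.ReLU()),
        ("stem_pool", nn.MaxPool2d()),
    ]
    cin = 64
    for stage, (planes, blocks, stride) in enumerate(
        [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)], start=1
    ):
        for b in range(1, blocks + 1):
            s = stride if b == 1 else 1
            layers.append((f"stage{stage}_block{b}", Bottleneck(cin, planes, s, rng)))
            cin = planes * 4
    layers.append(("gap", nn.GlobalAvgPool()))
    return nn.Sequential(layers), cin, "stage4_block2"


_MOBILENET_SETTINGS = [
    (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
    (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
]


def _build_mobilenetv2(rng: np.random.Generator) -> tuple[nn.Sequential, int, str]:
    layers: list[tuple[str, nn.Layer]] = [
        ("stem_conv", nn.Conv2d(3, 32, 3, stride=2, pad=1, rng=rng, bias=False)),
        ("stem_bn", nn.BatchNorm2d(32)),
        ("stem_relu", nn.ReLU6()),
    ]
    cin, idx = 32, 1
    for expand, cout, reps, stride in _MOBILENET_SETTINGS:
        for r in range(reps):
            s = stride if r == 0 else 1
            layers.append((f"block{idx}", InvertedResidual(cin, cout, s, expand, rng)))
            cin, idx = cout, idx + 1
    n_blocks = idx - 1
    layers += [
        ("head_conv", nn.Conv2d(cin, 1280, 1, rng=rng, bias=False)),
        ("head_bn", nn.BatchNorm2d(1280)),
        ("head_relu", nn.ReLU6()),
        ("gap", nn.GlobalAvgPool()),
    ]
    return nn.Sequential(layers), 1280, f"block{n_blocks - 1}"


def build_backbone(spec: BackboneSpec, seed: int = 0) -> tuple[nn.Sequential, int, str]:
    """Instantiate a backbone; returns (network, feature_dim, frozen_through)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    if spec.name == "tiny_test":
        net, dim, cut = _build_tiny(rng)
    elif spec.name == "vgg16":
        net, dim, cut = _build_vgg(_VGG16, rng)
    elif spec.name == "vgg19":
        net, dim, cut = _build_vgg(_VGG19, rng)
    elif spec.name == "resnet50":
        net, dim, cut = _build_resnet50(rng)
    else:
        net, dim, cut = _build_mobilenetv2(rng)
    if spec.pretrained:
        if spec.weights_path and Path(spec.weights_path).exists():
            _load_layer_arrays(net, np.load(spec.weights_path))
        else:
            warnings.warn(
                f"pretrained weights for {spec.name!r} are unavailable; "
                "falling back to random initialisation"
            )
    frozen_through = spec.frozen_through or cut
    return net, dim, frozen_through


# ---------------------------------------------------------------------------
# Fusion model
# ---------------------------------------------------------------------------


class FusionModel:
    """Backbone features concatenated with metadata, classified by an MLP head."""

    def __init__(
        self,
        spec: BackboneSpec,
        head_config: HeadConfig,
        metadata_dim: int = 5,
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.head_config = head_config
        self.metadata_dim = metadata_dim
        self.metadata_layout = tuple(METADATA_LAYOUT)
        self.seed = seed
        self.backbone, self.feature_dim, self.frozen_through = build_backbone(spec, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
        dims = [self.feature_dim + metadata_dim, *head_config.hidden_sizes, 1]
        head_layers: list[tuple[str, nn.Layer]] = []
        for i in range(len(dims) - 1):
            head_layers.append((f"fc{i + 1}", nn.Linear(dims[i], dims[i + 1], rng=rng)))
            if i < len(dims) - 2:
                head_layers.append((f"relu{i + 1}", nn.ReLU()))
                head_layers.append(
                    (f"drop{i + 1}", nn.Dropout(head_config.dropout, seed=seed + 101 + i))
                )
        self.head = nn.Sequential(head_layers)
        self.trained = False
        self._apply_freezing()

    # -- freezing ----------------------------------------------------------
    def _apply_freezing(self) -> None:
        names = [n for n, _ in self.backbone.layers]
        if self.frozen_through not in names:
            raise KeyError(
                f"frozen_through {self.frozen_through!r} is not a top-level layer; "
                f"available: {names}"
            )
        cut = names.index(self.frozen_through) + 1
        for _name, layer in self.backbone.layers[:cut]:
            layer.set_frozen(True)
        for _name, layer in self.backbone.layers[cut:]:
            layer.set_frozen(False)

    @property
    def fused_input_dim(self) -> int:
        return self.feature_dim + self.metadata_dim

    def frozen_prefix_and_suffix(self) -> tuple[nn.Sequential, nn.Sequential]:
        names = [n for n, _ in self.backbone.layers]
        cut_idx = names.index(self.frozen_through) + 1
        if cut_idx >= len(names):
            return self.backbone, nn.Sequential([])
        return self.backbone.split(names[cut_idx])

    def parameter_counts(self) -> dict[str, int]:
        frozen = trainable = 0
        for p in self.backbone.all_params() + self.head.all_params():
            n = int(np.prod(p.value.shape))
            if p.trainable:
                trainable += n
            else:
                frozen += n
        return {"frozen": frozen, "trainable": trainable}

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _to_nchw(images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[-1] in (1, 3) and arr.shape[1] not in (1, 3):
            arr = arr.transpose(0, 3, 1, 2)
        return np.ascontiguousarray(arr)

    def forward(self, images: np.ndarray, meta: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._to_nchw(images)
        meta = np.atleast_2d(np.asarray(meta, dtype=np.float32))
        if meta.shape[1] != self.metadata_dim:
            raise ValueError(
                f"metadata has {meta.shape[1]} entries; model expects {self.metadata_dim}"
            )
        feats = self.backbone.forward(x, train=train)
        fused = np.concatenate([feats, meta], axis=1)
        logits = self.head.forward(fused, train=train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.head.backward(np.asarray(dlogits, dtype=np.float32)[:, None])
        gfeat = g[:, : self.feature_dim]
        return self.backbone.backward(np.ascontiguousarray(gfeat))

    def predict_proba(self, images: np.ndarray, meta: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(images, meta, train=False))


def build_model(
    backbone: BackboneSpec,
    metadata_dim: int = 5,
    head: HeadConfig | None = None,
    seed: int = 0,
) -> FusionModel:
    """Construct the fusion classifier with frozen early backbone layers."""
    return FusionModel(backbone, head or HeadConfig(), metadata_dim=metadata_dim, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_head(
    model: FusionModel,
    data: AugmentedSet,
    cfg: TrainConfig,
    head: HeadConfig | None = None,
) -> FusionModel:
    """Fine-tune the unfrozen backbone tail and the head on augmented data.

    Minimises mean binary cross-entropy plus ``l2_lambda`` times the squared
    norm of the head's weight matrices.  The frozen prefix of the backbone
    is evaluated once per item and cached, so epochs only revisit the
    trainable tail.  Returns the same model, marked trained, with
    ``model.history`` holding per-epoch losses and the total number of image
    presentations (``epochs * len(data)``).
    """
    head = head or model.head_config
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    counts = data.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("training data must contain both classes")

    prefix, suffix = model.frozen_prefix_and_suffix()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)

    # cache the frozen-prefix activations once
    cached: list[np.ndarray] = []
    metas: list[np.ndarray] = []
    labels = np.zeros(len(data), dtype=np.float32)
    chunk = 32
    for start in range(0, len(data), chunk):
        idx = range(start, min(start + chunk, len(data)))
        imgs, ms, ys = zip(*(data[i] for i in idx))
        x = model._to_nchw(np.stack(imgs))
        out = prefix.forward(x, train=False) if prefix.layers else x
        cached.extend(np.ascontiguousarray(out[i]) for i in range(out.shape[0]))
        metas.extend(np.asarray(m, dtype=np.float32) for m in ms)
        labels[list(idx)] = ys

    trainable = [p for p in suffix.all_params() + model.head.all_params() if p.trainable]
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = nn.Adam(trainable, lr=cfg.learning_rate)
    head_weights = [
        layer.weight for _n, layer in model.head.layers if isinstance(layer, nn.Linear)
    ]

    epoch_losses: list[float] = []
    presented = 0
    n = len(data)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batch_losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            bidx = order[start : start + cfg.batch_size]
            x = np.stack([cached[i] for i in bidx])
            m = np.stack([metas[i] for i in bidx])
            y = labels[bidx]
            opt.zero_grad()
            feats = suffix.forward(x, train=True) if suffix.layers else x
            fused = np.concatenate([feats, m], axis=1)
            z = model.head.forward(fused, train=True)[:, 0]
            loss, dz = nn.bce_with_logits(z, y)
            if head.l2_lambda > 0:
                for w in head_weights:
                    loss += head.l2_lambda * float(np.sum(w.value.astype(np.float64) ** 2))
                    if w.trainable:
                        w.grad += 2.0 * head.l2_lambda * w.value
            g = model.head.backward(dz.astype(np.float32)[:, None])
            if suffix.layers:
                suffix.backward(np.ascontiguousarray(g[:, : model.feature_dim]))
            opt.step()
            batch_losses.append(loss)
            presented += len(bidx)
        epoch_losses.append(float(np.mean(batch_losses)))

    model.trained = True
    model.history = {"epoch_loss": epoch_losses, "images_presented": presented}
    return model


def predict(
    model: FusionModel,
    image: np.ndarray,
    meta: np.ndarray,
    image_id: str = "",
    true_label: str | None = None,
    sex: str | None = None,
    region: str | None = None,
) -> AgePrediction:
    """Score one image in evaluation mode (deterministic, dropout off)."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained; call train_head first")
    score = float(model.predict_proba(image[None], np.atleast_2d(meta))[0])
    return AgePrediction(
        image_id=image_id, score=score, true_label=true_label, sex=sex, region=region
    )


def predict_batch(
    model: FusionModel, items: Sequence[tuple[np.ndarray, np.ndarray]], batch_size: int = 32
) -> np.ndarray:
    """Scores for a list of (image, metadata) pairs, in input order."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained; call train_head first")
    scores = []
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        imgs = np.stack([c[0] for c in chunk])
        metas = np.stack([c[1] for c in chunk])
        scores.append(model.predict_proba(imgs, metas))
    return np.concatenate(scores) if scores else np.zeros(0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def _layer_arrays(net: nn.Sequential, prefix: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for path, layer in net.named_layers(prefix + "."):
        for i, p in enumerate(layer.params()):
            out[f"{path}|p{i}"] = p.value
        if isinstance(layer, nn.BatchNorm2d):
            out[f"{path}|rm"] = layer.running_mean
            out[f"{path}|rv"] = layer.running_var
    return out


def _load_layer_arrays(net: nn.Sequential, arrays, prefix: str = "") -> None:
    pref = prefix + "." if prefix else ""
    for path, layer in net.named_layers(pref):
        for i, p in enumerate(layer.params()):
            key = f"{path}|p{i}"
            if key in arrays:
                p.value[...] = arrays[key]
        if isinstance(layer, nn.BatchNorm2d):
            if f"{path}|rm" in arrays:
                layer.running_mean[...] = arrays[f"{path}|rm"]
                layer.running_var[...] = arrays[f"{path}|rv"]


def save_model(model: FusionModel, path: str | Path) -> None:
    """Write a checkpoint (architecture description + weights) as .npz."""
    meta = {
        "backbone": model.spec.name,
        "pretrained": model.spec.pretrained,
        "frozen_through": model.frozen_through,
        "metadata_layout": list(model.metadata_layout),
        "metadata_dim": model.metadata_dim,
        "head": {
            "hidden_sizes": list(model.head_config.hidden_sizes),
            "dropout": model.head_config.dropout,
            "l2_lambda": model.head_config.l2_lambda,
        },
        "seed": model.seed,
        "trained": bool(getattr(model, "trained", False)),
    }
    arrays = _layer_arrays(model.backbone, "backbone")
    arrays.update(_layer_arrays(model.head, "head"))
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> FusionModel:
    """Rebuild a model from a checkpoint; refuses a mismatched metadata layout."""
    data = np.load(Path(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    if tuple(meta["metadata_layout"]) != tuple(METADATA_LAYOUT):
        raise ValueError(
            "checkpoint metadata layout does not match this package's layout; "
            f"checkpoint: {meta['metadata_layout']}, expected: {list(METADATA_LAYOUT)}"
        )
    spec = BackboneSpec(
        name=meta["backbone"],
        pretrained=False,
        frozen_through=meta["frozen_through"],
    )
    head = HeadConfig(
        hidden_sizes=tuple(meta["head"]["hidden_sizes"]),
        dropout=meta["head"]["dropout"],
        l2_lambda=meta["head"]["l2_lambda"],
    )
    model = FusionModel(spec, head, metadata_dim=meta["metadata_dim"], seed=meta["seed"])
    _load_layer_arrays(model.backbone, data, "backbone")
    _load_layer_arrays(model.head, data, "head")
    model.trained = meta["trained"]
    return model
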