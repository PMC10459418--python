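"""Classifier backbones: declarative layer tables, shape inference, training.

Two architectures are shipped:

* ``sscnn_spec`` — the full single-stage CNN, an AlexNet-shaped stack of
  five convolutions and three fully connected layers on 227 x 227 x 3
  inputs, with the final dense layer sized to the label set.  It exists as
  a faithful declarative record (and its printed layer sizes are a shape-
  inference test case); training it is possible through the same engine but
  is far beyond desk scale.
* ``tiny_spec`` — a 3-conv + 1-dense backbone on 32-pixel inputs used for
  all desk-scale experiments.  Pipeline logic is backbone-agnostic.

Training is minibatch stochastic gradient descent with momentum at a
configured learning rate, validating after every epoch; the returned model
is the checkpoint of the earliest epoch attaining the best validation
accuracy.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "sscnn_spec",
    "tiny_spec",
    "infer_shapes",
    "prepare_batch",
    "train",
    "predict",
]


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table."""

    name: str
    kind: str  # input | conv | maxpool | dense
    maps: int | None = None  # channel count (input/conv/maxpool)
    kernel: int | None = None
    stride: int | None = None
    padding: int | None = None
    activation: str = "none"  # relu | softmax | none
    out_units: int | None = None  # dense only

    def __post_init__(self) -> None:
        if self.kind not in ("input", "conv", "maxpool", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "maxpool"):
            if self.kernel is None or self.stride is None or self.padding is None:
                raise ValueError(f"layer {self.name}: conv/pool need kernel/stride/padding")
            if self.stride < 1:
                raise ValueError(f"layer {self.name}: stride must be >= 1")
        elif self.kernel is not None or self.stride is not None:
            raise ValueError(f"layer {self.name}: kernel/stride only valid on conv/pool")
        if self.kind == "dense" and self.out_units is None:
            raise ValueError(f"layer {self.name}: dense needs out_units")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer table plus input geometry and the class count."""

    layers: tuple[LayerSpec, ...]
    input_side: int
    input_channels: int
    n_classes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers or self.layers[0].kind != "input":
            raise ValueError("first layer must be the input layer")
        last = self.layers[-1]
        if last.kind != "dense" or last.out_units != self.n_classes:
            raise ValueError("last layer must be dense with out_units = n_classes")
        if last.activation != "softmax":
            raise ValueError("last layer must end in softmax")

    def digest(self) -> str:
        blob = json.dumps(
            [vars(l) for l in self.layers]
            + [self.input_side, self.input_channels, self.n_classes],
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def sscnn_spec(n_classes: int) -> ArchitectureSpec:
    """The single-stage CNN: AlexNet-shaped table with an ``n_classes`` head.

    Five convolutions (96/256/384/384/256 maps) interleaved with three max
    pools, then Fc6/Fc7 at 4096 units and the softmax head, on 227-pixel
    RGB inputs.
    """
    if n_classes < 2:
        raise ValueError("a classifier needs at least 2 classes")
    L = LayerSpec
    layers = (
        L("Input", "input", maps=3),
        L("Conv1", "conv", maps=96, kernel=11, stride=4, padding=0, activation="relu"),
        L("Pool1", "maxpool", maps=96, kernel=3, stride=2, padding=0),
        L("Conv2", "conv", maps=256, kernel=5, stride=1, padding=2, activation="relu"),
        L("Pool2", "maxpool", maps=256, kernel=3, stride=2, padding=0),
        L("Conv3", "conv", maps=384, kernel=3, stride=1, padding=1, activation="relu"),
        L("Conv4", "conv", maps=384, kernel=3, stride=1, padding=1, activation="relu"),
        L("Conv5", "conv", maps=256, kernel=3, stride=1, padding=1, activation="relu"),
        L("Pool5", "maxpool", maps=256, kernel=3, stride=2, padding=0),
        L("Fc6", "dense", out_units=4096, activation="relu"),
        L("Fc7", "dense", out_units=4096, activation="relu"),
        L("Fc8", "dense", out_units=n_classes, activation="softmax"),
    )
    return ArchitectureSpec(layers, input_side=227, input_channels=3, n_classes=n_classes)


def tiny_spec(n_classes: int, input_side: int = 32) -> ArchitectureSpec:
    """Desk-scale backbone: three stride-2 convolutions and a softmax head."""
    if n_classes < 2:
        raise ValueError("a classifier needs at least 2 classes")
    L = LayerSpec
    layers = (
        L("Input", "input", maps=3),
        L("Conv1", "conv", maps=8, kernel=3, stride=2, padding=1, activation="relu"),
        L("Conv2", "conv", maps=16, kernel=3, stride=2, padding=1, activation="relu"),
        L("Conv3", "conv", maps=32, kernel=3, stride=2, padding=1, activation="relu"),
        L("Fc", "dense", out_units=n_classes, activation="softmax"),
    )
    return ArchitectureSpec(layers, input_side=input_side, input_channels=3, n_classes=n_classes)


def infer_shapes(spec: ArchitectureSpec) -> dict[str, int]:
    """Spatial side after each layer: floor((n + 2p - k)/s) + 1 for conv/pool.

    Dense layers report side 1.  A non-positive intermediate side raises,
    naming the offending layer.
    """
    sides: dict[str, int] = {}
    side = spec.input_side
    for layer in spec.layers:
        if layer.kind == "input":
            pass
        elif layer.kind in ("conv", "maxpool"):
            side = (side + 2 * layer.padding - layer.kernel) // layer.stride + 1
            if side <= 0:
                raise ValueError(f"layer {layer.name}: non-positive output side {side}")
        else:  # dense
            side = 1
        sides[layer.name] = side
    return sides


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (momentum SGD, per-epoch validation)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    momentum: float = 0.9
    max_epochs: int = 100
    max_iterations: int | None = None  # optional iteration cap
    seed: int = 0
    pretrained_init: bool = False  # hook for externally supplied weights

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def with_seed(self, seed: int) -> "TrainConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedModel:
    """A trained classifier: parameters, label order, and training curves."""

    spec: ArchitectureSpec
    labels: tuple[str, ...]
    params: list[np.ndarray]
    history: dict[str, list[float]]
    best_epoch: int  # 1-based, earliest epoch attaining max validation accuracy
    seed: int

    @property
    def input_side(self) -> int:
        return self.spec.input_side

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "params.npz", *self.params)
        meta = {
            "architecture_digest": self.spec.digest(),
            "layers": [vars(l) for l in self.spec.layers],
            "input_side": self.spec.input_side,
            "input_channels": self.spec.input_channels,
            "n_classes": self.spec.n_classes,
            "labels": list(self.labels),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "seed": self.seed,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        layers = tuple(LayerSpec(**{k: v for k, v in l.items()}) for l in meta["layers"])
        spec = ArchitectureSpec(
            layers, meta["input_side"], meta["input_channels"], meta["n_classes"]
        )
        with np.load(d / "params.npz") as z:
            params = [z[k] for k in z.files]
        return cls(
            spec=spec,
            labels=tuple(meta["labels"]),
            params=params,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            seed=meta["seed"],
        )


def _build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> _nn.Network:
    sides = infer_shapes(spec)
    layers: list[_nn.Layer] = []
    channels = spec.input_channels
    side = spec.input_side
    flat = False
    for ls in spec.layers:
        if ls.kind == "input":
            continue
        if ls.kind == "conv":
            layers.append(_nn.Conv2D(channels, ls.maps, ls.kernel, ls.stride, ls.padding, rng))
            channels, side = ls.maps, sides[ls.name]
            if ls.activation == "relu":
                layers.append(_nn.ReLU())
        elif ls.kind == "maxpool":
            layers.append(_nn.MaxPool2D(ls.kernel, ls.stride))
            side = sides[ls.name]
        else:  # dense
            if not flat:
                layers.append(_nn.Flatten())
                n_in = channels * side * side
                flat = True
            layers.append(_nn.Dense(n_in, ls.out_units, rng))
            n_in = ls.out_units
            if ls.activation == "relu":
                layers.append(_nn.ReLU())
    return _nn.Network(layers)


def prepare_batch(images: np.ndarray, side: int) -> np.ndarray:
    """Resize a (n, H, W, 3) float stack to the backbone input side, NCHW.

    Bilinear interpolation (with anti-aliasing when downscaling); a no-op
    reorder when the images already match the side.
    """
    from skimage.transform import resize

    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W, 3) images, got shape {images.shape}")
    n, h, w = images.shape[:3]
    if (h, w) != (side, side):
        out = np.empty((n, side, side, 3), dtype=np.float32)
        for i in range(n):
            out[i] = resize(
                images[i], (side, side), order=1, anti_aliasing=(h > side), preserve_range=True
            )
        images = out
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def _accuracy_and_loss(net: _nn.Network, x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    correct, loss_sum = 0, 0.0
    for k in range(0, len(x), batch):
        logits = net.forward(x[k : k + batch], train=False)
        probs = _nn.softmax(logits)
        yb = y[k : k + batch]
        correct += int((probs.argmax(axis=1) == yb).sum())
        loss_sum += _nn.cross_entropy(probs, yb) * len(yb)
    return correct / len(x), loss_sum / len(x)


def train(
    train_images: np.ndarray,
    train_labels: Sequence[str],
    val_images: np.ndarray,
    val_labels: Sequence[str],
    spec: ArchitectureSpec,
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Fit the backbone with momentum SGD, returning the best-epoch checkpoint.

    Images are (n, H, W, 3) floats in [0, 1]; they are resized to the spec's
    input side here.  Validation runs after every epoch; the kept checkpoint
    is the earliest epoch with the maximum validation accuracy.
    """
    train_labels = [str(l) for l in train_labels]
    val_labels = [str(l) for l in val_labels]
    if len(train_labels) == 0 or len(val_labels) == 0:
        raise ValueError("training and validation splits must be non-empty")
    labels = tuple(sorted(set(train_labels)))
    if len(labels) < 2:
        raise ValueError("training set has a single class")
    extra = set(val_labels) - set(labels)
    if extra:
        raise ValueError(f"validation labels {sorted(extra)} absent from training set")
    if spec.n_classes != len(labels):
        raise ValueError(f"spec head has {spec.n_classes} classes but data has {len(labels)}")

    index = {lab: k for k, lab in enumerate(labels)}
    ytr = np.array([index[l] for l in train_labels])
    yva = np.array([index[l] for l in val_labels])
    xtr = prepare_batch(train_images, spec.input_side)
    xva = prepare_batch(val_images, spec.input_side)

    rng = np.random.default_rng(config.seed)
    net = _build_network(spec, rng)
    opt = _nn.MomentumSGD(net.parameters(), config.learning_rate, config.momentum)

    history: dict[str, list[float]] = {
        "train_accuracy": [],
        "train_loss": [],
        "val_accuracy": [],
        "val_loss": [],
    }
    best_acc, best_epoch, best_state = -1.0, 0, net.get_state()
    iterations = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xtr))
        epoch_loss, epoch_correct = 0.0, 0
        for k in range(0, len(order), config.batch_size):
            if config.max_iterations is not None and iterations >= config.max_iterations:
                break
            idx = order[k : k + config.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logits = net.forward(xb, train=True)
            probs = _nn.softmax(logits)
            epoch_loss += _nn.cross_entropy(probs, yb) * len(yb)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            net.backward(dlogits.astype(np.float32) / len(yb))
            opt.step(net.gradients())
            iterations += 1
        history["train_accuracy"].append(epoch_correct / len(xtr))
        history["train_loss"].append(epoch_loss / len(xtr))
        va, vl = _accuracy_and_loss(net, xva, yva, config.batch_size)
        history["val_accuracy"].append(va)
        history["val_loss"].append(vl)
        if va > best_acc:  # strict: keeps the earliest epoch on ties
            best_acc, best_epoch, best_state = va, epoch, net.get_state()
        if config.max_iterations is not None and iterations >= config.max_iterations:
            break

    logger.info(
        "training done: best val accuracy %.4f at epoch %d/%d",
        best_acc,
        best_epoch,
        len(history["val_accuracy"]),
    )
    return TrainedModel(
        spec=spec,
        labels=labels,
        params=best_state,
        history=history,
        best_epoch=best_epoch,
        seed=config.seed,
    )


def predict(model: TrainedModel, images: np.ndarray, batch_size: int = 64) -> tuple[list[str], np.ndarray]:
    """Labels (argmax) and softmax score vectors for a stack of images.

    Images must already be at the model's input side (crop and resize happen
    upstream); a shape or channel mismatch is an error.  An empty batch
    yields empty outputs.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.size == 0:
        return [], np.zeros((0, len(model.labels)), dtype=np.float32)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (n, side, side, 3) images, got {images.shape}")
    side = model.input_side
    if images.shape[1] != side or images.shape[2] != side:
        raise ValueError(
            f"images are {images.shape[1]}x{images.shape[2]} but the model "
            f"expects {side}x{side}; resize upstream"
        )
    rng = np.random.default_rng(0)  # init overwritten immediately
    net = _build_network(model.spec, rng)
    net.set_state(model.params)
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2))
    scores = []
    for k in range(0, len(x), batch_size):
        scores.append(_nn.softmax(net.forward(x[k : k + batch_size], train=False)))
    scores = np.concatenate(scores, axis=0)
    labels = [model.labels[i] for i in scores.argmax(axis=1)]
    return labels, scores
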