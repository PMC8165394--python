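"""Inception-ResNet-style image classifier: architecture, training, prediction.

The network follows the canonical Inception-ResNet-v2 layout: a stem of nine
convolution layers and two max-pooling layers, then three groups of residual
inception blocks (A with stacked 3x3 branches, B with the asymmetric 1x7/7x1
pair, C with 1x3/3x1), separated by two downsampling reduction modules, and
finished by global average pooling and a softmax head. Every block branch
starts with 1x1 convolutions before the larger filters; block outputs are
added back to the block input through a linear 1x1 projection scaled by 0.1
(the customary residual stabilization). Channel widths scale with
``width_scale`` so a ``tiny`` profile trains on one CPU in minutes; block
repetition counts default to the canonical (5, 10, 5).

Training uses mini-batch Adam (default moments) with categorical
cross-entropy; after each epoch the model is scored by macro-F1 on the
validation set, and the best-scoring epoch snapshot is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import (Adam, BatchNorm2d, Branches, Conv2d, Dense, GlobalAvgPool,
                  MaxPool2d, Module, ReLU, ResidualInception, Sequential,
                  cross_entropy, softmax)
from .records import ClassLabelSet

MIN_INPUT_SIZE = 32  # the stem + two reductions downsample by 32


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters."""

    input_size: int = 299
    n_classes: int = 9
    block_counts: Tuple[int, int, int] = (5, 10, 5)
    width_scale: float = 1.0
    profile: str = "full"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(b < 1 for b in self.block_counts):
            raise ValueError("block_counts must all be >= 1")
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must lie in (0, 1]")
        if self.input_size < MIN_INPUT_SIZE:
            raise ValueError(
                f"input_size {self.input_size} too small for the "
                f"downsampling chain; minimum is {MIN_INPUT_SIZE}")

    @staticmethod
    def tiny(n_classes: int = 3, input_size: int = 75) -> "ArchConfig":
        """Desk-scale profile: trains in minutes on one CPU."""
        return ArchConfig(input_size=input_size, n_classes=n_classes,
                          block_counts=(1, 2, 1), width_scale=0.25,
                          profile="tiny")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults mirror the reference setup)."""

    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 10
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    pretrained_weights: Optional[str] = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _conv_bn_relu(in_c, out_c, kh, kw, stride, rng) -> Sequential:
    return Sequential(Conv2d(in_c, out_c, kh, kw, stride, rng, bias=False),
                      BatchNorm2d(out_c), ReLU())


class Network(Module):
    """Assembled network plus bookkeeping (channel trace, param count)."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = lambda c: max(1, int(round(c * config.width_scale)))  # noqa: E731

        def block_a(in_c):
            branches = Branches(
                _conv_bn_relu(in_c, w(32), 1, 1, 1, rng),
                Sequential(_conv_bn_relu(in_c, w(32), 1, 1, 1, rng),
                           _conv_bn_relu(w(32), w(32), 3, 3, 1, rng)),
                Sequential(_conv_bn_relu(in_c, w(32), 1, 1, 1, rng),
                           _conv_bn_relu(w(32), w(48), 3, 3, 1, rng),
                           _conv_bn_relu(w(48), w(64), 3, 3, 1, rng)))
            cat = w(32) + w(32) + w(64)
            return ResidualInception(branches, Conv2d(cat, in_c, 1, 1, 1, rng))

        def block_b(in_c):
            branches = Branches(
                _conv_bn_relu(in_c, w(192), 1, 1, 1, rng),
                Sequential(_conv_bn_relu(in_c, w(128), 1, 1, 1, rng),
                           _conv_bn_relu(w(128), w(160), 1, 7, 1, rng),
                           _conv_bn_relu(w(160), w(192), 7, 1, 1, rng)))
            cat = w(192) + w(192)
            return ResidualInception(branches, Conv2d(cat, in_c, 1, 1, 1, rng))

        def block_c(in_c):
            branches = Branches(
                _conv_bn_relu(in_c, w(192), 1, 1, 1, rng),
                Sequential(_conv_bn_relu(in_c, w(192), 1, 1, 1, rng),
                           _conv_bn_relu(w(192), w(224), 1, 3, 1, rng),
                           _conv_bn_relu(w(224), w(256), 3, 1, 1, rng)))
            cat = w(192) + w(256)
            return ResidualInception(branches, Conv2d(cat, in_c, 1, 1, 1, rng))

        stem = Sequential(
            _conv_bn_relu(3, w(32), 3, 3, 2, rng),
            _conv_bn_relu(w(32), w(32), 3, 3, 1, rng),
            _conv_bn_relu(w(32), w(64), 3, 3, 1, rng),
            MaxPool2d(3, 2),
            _conv_bn_relu(w(64), w(80), 1, 1, 1, rng),
            _conv_bn_relu(w(80), w(192), 3, 3, 1, rng),
            MaxPool2d(3, 2),
            _conv_bn_relu(w(192), w(64), 1, 1, 1, rng),
            _conv_bn_relu(w(64), w(64), 1, 7, 1, rng),
            _conv_bn_relu(w(64), w(64), 7, 1, 1, rng),
            _conv_bn_relu(w(64), w(192), 3, 3, 1, rng),
        )
        stem_out = w(192)

        nA, nB, nC = config.block_counts
        layers: List[Module] = [stem]
        layers += [block_a(stem_out) for _ in range(nA)]

        # reduction A: maxpool | 3x3 stride-2 | 1x1 -> 3x3 -> 3x3 stride-2
        red_a = Branches(
            MaxPool2d(3, 2),
            _conv_bn_relu(stem_out, w(384), 3, 3, 2, rng),
            Sequential(_conv_bn_relu(stem_out, w(256), 1, 1, 1, rng),
                       _conv_bn_relu(w(256), w(256), 3, 3, 1, rng),
                       _conv_bn_relu(w(256), w(384), 3, 3, 2, rng)))
        b_in = stem_out + w(384) + w(384)
        layers.append(red_a)
        layers += [block_b(b_in) for _ in range(nB)]

        # reduction B: maxpool | three stride-2 conv branches
        red_b = Branches(
            MaxPool2d(3, 2),
            Sequential(_conv_bn_relu(b_in, w(256), 1, 1, 1, rng),
                       _conv_bn_relu(w(256), w(384), 3, 3, 2, rng)),
            Sequential(_conv_bn_relu(b_in, w(256), 1, 1, 1, rng),
                       _conv_bn_relu(w(256), w(288), 3, 3, 2, rng)),
            Sequential(_conv_bn_relu(b_in, w(256), 1, 1, 1, rng),
                       _conv_bn_relu(w(256), w(288), 3, 3, 1, rng),
                       _conv_bn_relu(w(288), w(320), 3, 3, 2, rng)))
        c_in = b_in + w(384) + w(288) + w(320)
        layers.append(red_b)
        layers += [block_c(c_in) for _ in range(nC)]

        layers += [GlobalAvgPool(), Dense(c_in, config.n_classes, rng)]
        self.net = Sequential(*layers)
        self.feature_channels = c_in

    def params(self):
        return self.net.params()

    def buffers(self):
        return self.net.buffers()

    def forward(self, x, train):
        return self.net.forward(x, train)

    def backward(self, dout):
        return self.net.backward(dout)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities for NHWC images in [0, 1] (eval mode)."""
        x = _to_nchw(images, self.config.input_size)
        if x.shape[0] == 0:
            return np.zeros((0, self.config.n_classes))
        out = [softmax(self.forward(x[i:i + batch_size], train=False))
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)


def build_network(config: ArchConfig, seed: int = 0) -> Network:
    """Construct the network; parameter count available via
    ``Network.n_parameters``."""
    return Network(config, seed=seed)


def _to_nchw(images: np.ndarray, input_size: int) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError("images must be (n, H, W, 3)")
    if images.shape[1] != input_size or images.shape[2] != input_size:
        raise ValueError(
            f"image size {images.shape[1]}x{images.shape[2]} does not match "
            f"network input {input_size}x{input_size}")
    return images.transpose(0, 3, 1, 2)


@dataclass
class TrainedModel:
    """Best-epoch network snapshot plus training history."""

    network: Network
    config: ArchConfig
    classes: ClassLabelSet
    log: List[dict] = field(default_factory=list)

    def predict(self, images: np.ndarray):
        """Per-sample probabilities and argmax labels (ties -> lower index)."""
        proba = self.network.predict_proba(images)
        labels = [self.classes.names[i] for i in proba.argmax(axis=1)] \
            if proba.shape[0] else []
        return proba, labels

    def save(self, path) -> Path:
        path = Path(path)
        state = _nn.get_state(self.network)
        np.savez_compressed(
            path.with_suffix(".npz"),
            **{f"s{i}": arr for i, arr in enumerate(state)})
        meta = {
            "config": {"input_size": self.config.input_size,
                       "n_classes": self.config.n_classes,
                       "block_counts": list(self.config.block_counts),
                       "width_scale": self.config.width_scale,
                       "profile": self.config.profile},
            "classes": list(self.classes.names),
            "log": self.log,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        config = ArchConfig(input_size=cfg["input_size"],
                            n_classes=cfg["n_classes"],
                            block_counts=tuple(cfg["block_counts"]),
                            width_scale=cfg["width_scale"],
                            profile=cfg["profile"])
        network = Network(config)
        with np.load(path.with_suffix(".npz")) as data:
            state = [data[f"s{i}"] for i in range(len(data.files))]
        _nn.set_state(network, state)
        return cls(network=network, config=config,
                   classes=ClassLabelSet(meta["classes"]), log=meta["log"])


def _encode_labels(labels: Sequence[str], classes: ClassLabelSet) -> np.ndarray:
    return np.array([classes.index(l) for l in labels])


def train(network: Network, train_set, val_set, config: TrainConfig,
          classes: ClassLabelSet) -> TrainedModel:
    """Mini-batch training with per-epoch validation macro-F1 model selection.

    ``train_set``/``val_set`` are ``(images NHWC, labels list)`` pairs.
    Reproducible: the seed fixes initialization-independent batch order and
    the same seed yields the same training log to floating-point tolerance.
    """
    from .evaluation import compute_metrics

    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(y_train) == 0:
        raise ValueError("empty training set")
    if len(y_val) == 0:
        raise ValueError("empty validation set")
    x_train = _to_nchw(np.asarray(x_train), network.config.input_size)
    yi_train = _encode_labels(y_train, classes)
    if x_train.shape[0] != yi_train.shape[0]:
        raise ValueError("image/label count mismatch")
    x_val = np.asarray(x_val)

    if config.pretrained_weights:
        with np.load(config.pretrained_weights) as data:
            _nn.set_state(network,
                          [data[f"s{i}"] for i in range(len(data.files))])

    opt = Adam(network.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log: List[dict] = []
    best_state, best_f1 = _nn.get_state(network), -1.0

    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            opt.zero_grad()
            logits = network.forward(x_train[idx], train=True)
            loss, dlogits = cross_entropy(logits, yi_train[idx])
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        proba = network.predict_proba(x_val)
        pred = [classes.names[i] for i in proba.argmax(axis=1)]
        val_f1 = compute_metrics(list(y_val), pred, classes).macro_f1
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_macro_f1": float(val_f1)})
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = _nn.get_state(network)

    _nn.set_state(network, best_state)
    return TrainedModel(network=network, config=network.config,
                        classes=classes, log=log)


def predict(model: TrainedModel, images: np.ndarray):
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(images)
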