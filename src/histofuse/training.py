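"""Backbone construction and training of the fused-input classifier.

``build_backbone`` provides three convolutional architectures: ``tiny``
(two conv blocks, trains in seconds on one CPU, used throughout the test
suite and the synthetic benchmark), ``vgg16-like`` (the 16-layer
configuration with a 4096-wide penultimate layer) and ``inceptionv3-like``
(mixed 1x1/3x3/5x5 parallel branches with a 2048-wide penultimate layer).
All end in a dropout layer followed by a K-way normalized-score output.

Training uses Adamax with categorical cross-entropy, runs a fixed epoch
budget, and restores the parameters of the epoch with the best validation
accuracy (ties broken toward the earliest epoch).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .fusion import FusedSample
from .nn import (Adamax, Conv2D, Dense, Dropout, Flatten, GlobalAvgPool,
                 Layer, MaxPool2, Parallel, ReLU, Sequential,
                 softmax_cross_entropy)

logger = logging.getLogger("histofuse")

BACKBONE_SPECS = ("tiny", "vgg16-like", "inceptionv3-like")


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    Defaults are the full-scale settings: Adamax at learning rate 1e-6,
    dropout 0.25, batch size 140, 50 epochs.  Desk-scale experiments on the
    synthetic benchmark override the learning rate (see docs/methods.md).
    """

    optimizer: str = "adamax"
    learning_rate: float = 1e-6
    dropout: float = 0.25
    batch_size: int = 140
    epochs: int = 50
    seed: int = 0
    num_classes: int = 24

    def __post_init__(self):
        if self.optimizer != "adamax":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 1 <= self.batch_size <= 10 ** 6:
            raise ValueError("batch_size must be in [1, 1e6]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves; ``best_epoch`` is 1-based."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def best_val_acc(self) -> float:
        return self.val_acc[self.best_epoch - 1]

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,val_loss,val_acc"]
        for i, (tl, vl, va) in enumerate(
                zip(self.train_loss, self.val_loss, self.val_acc), start=1):
            lines.append(f"{i},{tl:.10f},{vl:.10f},{va:.10f}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# backbones


def _tiny(input_side: int, num_classes: int, dropout: float,
          rng: np.random.Generator) -> tuple[list[Layer], int, int]:
    layers: list[Layer] = [
        Conv2D(1, 8, 3, rng), ReLU(), MaxPool2(),
        Conv2D(8, 16, 3, rng), ReLU(),
        GlobalAvgPool(),
        Dense(16, 32, rng), ReLU(),
    ]
    head = [Dropout(dropout), Dense(32, num_classes, rng)]
    return layers + head, 32, len(layers)


def _vgg16_like(input_side: int, num_classes: int, dropout: float,
                rng: np.random.Generator) -> tuple[list[Layer], int, int]:
    # the 13-conv configuration (3x3 stride 1, five 2x2 pools), single channel
    cfg = [(1, 64), (64, 64), "P", (64, 128), (128, 128), "P",
           (128, 256), (256, 256), (256, 256), "P",
           (256, 512), (512, 512), (512, 512), "P",
           (512, 512), (512, 512), (512, 512), "P"]
    layers: list[Layer] = []
    side = input_side
    for item in cfg:
        if item == "P":
            layers.append(MaxPool2())
            side //= 2
        else:
            cin, cout = item
            layers += [Conv2D(cin, cout, 3, rng), ReLU()]
    if side < 1:
        raise ValueError(f"input side {input_side} too small for vgg16-like")
    flat = side * side * 512
    layers += [Flatten(),
               Dense(flat, 4096, rng), ReLU(),
               Dense(4096, 4096, rng), ReLU()]
    head = [Dropout(dropout), Dense(4096, num_classes, rng)]
    return layers + head, 4096, len(layers)


def _inception_block(cin: int, c1: int, c3: int, c5: int,
                     rng: np.random.Generator) -> Parallel:
    return Parallel([
        [Conv2D(cin, c1, 1, rng), ReLU()],
        [Conv2D(cin, c3, 3, rng), ReLU()],
        [Conv2D(cin, c5, 5, rng), ReLU()],
    ])


def _inceptionv3_like(input_side: int, num_classes: int, dropout: float,
                      rng: np.random.Generator) -> tuple[list[Layer], int, int]:
    layers: list[Layer] = [
        Conv2D(1, 16, 3, rng), ReLU(), MaxPool2(),
        _inception_block(16, 8, 16, 8, rng),   # -> 32 channels
        MaxPool2(),
        _inception_block(32, 16, 32, 16, rng),  # -> 64 channels
        GlobalAvgPool(),
        Dense(64, 2048, rng), ReLU(),
    ]
    head = [Dropout(dropout), Dense(2048, num_classes, rng)]
    return layers + head, 2048, len(layers)


_BUILDERS = {"tiny": _tiny, "vgg16-like": _vgg16_like,
             "inceptionv3-like": _inceptionv3_like}


def build_backbone(spec: str, input_side: int, num_classes: int,
                   dropout: float = 0.25, seed: int = 0) -> Sequential:
    """Construct a convolutional backbone with a K-way softmax output.

    The penultimate layer (the activation just before the dropout + output
    head) is the feature layer used by the frozen-extractor role.
    """
    if spec not in _BUILDERS:
        raise ValueError(
            f"unknown backbone spec {spec!r}; valid specs: {BACKBONE_SPECS}"
        )
    if input_side < 1:
        raise ValueError("input_side must be >= 1")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    rng = np.random.default_rng([seed, zlib.crc32(spec.encode())])
    layers, penultimate, head_start = _BUILDERS[spec](
        input_side, num_classes, dropout, rng)
    return Sequential(layers, spec=spec, input_side=input_side,
                      num_classes=num_classes, penultimate_width=penultimate,
                      head_start=head_start, dropout=dropout, seed=seed)


# ---------------------------------------------------------------------------
# training


def stack_samples(samples: Sequence[FusedSample]) -> tuple[np.ndarray, np.ndarray]:
    """(N, 1, side, side) float32 maps and int labels from fused samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample batch")
    maps = np.stack([s.conv_map for s in samples]).astype(np.float32)[:, None]
    labels = np.array(
        [s.label.index if hasattr(s.label, "index") else int(s.label)
         for s in samples],
        dtype=np.int64,
    )
    return maps, labels


def _evaluate(model: Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.forward_logits(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]


def train(model: Sequential, train_set: Sequence[FusedSample],
          val_set: Sequence[FusedSample],
          config: TrainConfig) -> tuple[Sequential, TrainingHistory]:
    """Train for exactly ``config.epochs`` epochs; restore the best epoch.

    All randomness (shuffling, dropout masks) is drawn from a generator
    seeded with ``config.seed``, so identical (data, config, seed) runs
    produce identical histories and weights on a single-threaded CPU.
    """
    xtr, ytr = stack_samples(train_set)
    xval, yval = stack_samples(val_set)
    for name, y in (("train", ytr), ("validation", yval)):
        bad = y[(y < 0) | (y >= config.num_classes)]
        if bad.size:
            raise ValueError(
                f"{name} labels outside [0, {config.num_classes - 1}]: "
                f"{sorted(set(bad.tolist()))}"
            )
    rng = np.random.default_rng(config.seed)
    opt = Adamax(model.parameters(), config.learning_rate)
    history = TrainingHistory()
    best_acc, best_state = -1.0, None
    n = xtr.shape[0]
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            logits = model.forward_logits(xtr[idx], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
        val_loss, val_acc = _evaluate(model, xval, yval, config.batch_size)
        history.train_loss.append(epoch_loss / n)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc = val_acc
            best_state = model.get_state()
            history.best_epoch = epoch
        logger.debug("epoch %d: train_loss=%.4f val_loss=%.4f val_acc=%.4f",
                     epoch, history.train_loss[-1], val_loss, val_acc)
    model.set_state(best_state)
    return model, history


def predict(model: Sequential,
            samples: Sequence[FusedSample] | np.ndarray) -> np.ndarray:
    """Predicted class index per sample (argmax; ties -> lowest index)."""
    if isinstance(samples, np.ndarray):
        x = samples
    else:
        x, _ = stack_samples(samples)
    scores = model.predict_proba(x)
    return scores.argmax(axis=1)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: Sequential, path: str | Path,
                    extra_meta: dict | None = None) -> None:
    """Serialize weights + architecture metadata to a portable .npz file."""
    meta = {
        "spec": model.spec,
        "input_side": model.input_side,
        "num_classes": model.num_classes,
        "dropout": model.dropout,
        "seed": model.seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(Path(path), meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Sequential, dict]:
    """Rebuild the architecture from metadata and load its weights."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n_params = len([k for k in data.files if k.startswith("p")])
        state = [data[f"p{i}"] for i in range(n_params)]
    model = build_backbone(meta["spec"], meta["input_side"],
                           meta["num_classes"], meta["dropout"], meta["seed"])
    model.set_state(state)
    return model, meta
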