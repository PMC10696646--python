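"""Compact 2D CNN beat classifiers.

Two architectures are provided.  The *proposed* network is a small
three-block CNN for 180x64 beat images:

    Conv(8, 6x6) -> pool -> Conv(16, 5x5) -> pool -> Conv(32, 4x4) -> pool
    -> Dense 512 -> Dense 256 -> Dense 128 -> Dense 15 (softmax)

The *baseline* is a reduced VGG-style network for 128x128 images with
three [Conv-BN-Conv-BN-pool] blocks at 8/16/32 filters and a single
Dense-512 + BatchNorm head.  (The printed baseline architecture lists a
max-pooling layer after that head; pooling is undefined on a flat
vector, so it is represented as an explicit no-op.)

Convolutions use "same" padding, pools are 2x2 stride 2, training is
Adam (1e-3) on categorical cross-entropy.  Everything is plain numpy,
so a fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .ecg_io import CLASS_LABELS
from .metrics import confusion, summarize
from .preprocess import BeatImage

__all__ = [
    "ClassifierModel", "Prediction", "ShapeError",
    "build_proposed", "build_baseline", "train", "predict", "predict_batch",
    "save_model", "load_model", "BeatClassifier", "TrainingResults",
]

N_CLASSES = len(CLASS_LABELS)


class ShapeError(ValueError):
    """Input geometry does not match the network's input shape."""


@dataclass(frozen=True)
class Prediction:
    """One classification: argmax class, its probability, full softmax."""

    class_index: int
    confidence: float
    full_distribution: np.ndarray

    @property
    def symbol(self) -> str:
        return CLASS_LABELS[self.class_index]


@dataclass
class ClassifierModel:
    """Architecture + parameters + the ordered label vocabulary."""

    architecture_id: str
    input_shape: tuple[int, int, int]  # (width, height, 1)
    network: nn.Sequential
    label_vocabulary: tuple[str, ...] = CLASS_LABELS
    training_meta: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.input_shape[0]

    @property
    def height(self) -> int:
        return self.input_shape[1]

    @property
    def num_params(self) -> int:
        return self.network.num_params

    def layer_summary(self) -> list[str]:
        return [type(layer).__name__ for layer in self.network.layers]


def build_proposed(seed: int = 0) -> ClassifierModel:
    """The compact three-block CNN for 180x64 beat images."""
    rng = np.random.default_rng(seed)
    w, h = 180, 64
    # after three 2x2 pools: 64x180 -> 32x90 -> 16x45 -> 8x22
    flat = 32 * (h // 8) * (w // 2 // 2 // 2)
    net = nn.Sequential([
        nn.Conv2D(1, 8, 6, rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(8, 16, 5, rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(16, 32, 4, rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Flatten(),
        nn.Dense(flat, 512, rng), nn.ReLU(),
        nn.Dense(512, 256, rng), nn.ReLU(),
        nn.Dense(256, 128, rng), nn.ReLU(),
        nn.Dense(128, N_CLASSES, rng),
    ])
    return ClassifierModel("proposed", (w, h, 1), net,
                           training_meta={"seed": seed, "epochs": 0})


def build_baseline(seed: int = 0) -> ClassifierModel:
    """The reduced VGG-style baseline for 128x128 beat images."""
    rng = np.random.default_rng(seed)
    w = h = 128
    layers: list[nn.Layer] = []
    in_c = 1
    for k in (8, 16, 32):
        layers += [
            nn.Conv2D(in_c, k, 3, rng), nn.BatchNorm(k), nn.ReLU(),
            nn.Conv2D(k, k, 3, rng), nn.BatchNorm(k), nn.ReLU(),
            nn.MaxPool2D(),
        ]
        in_c = k
    flat = 32 * (h // 8) * (w // 8)
    layers += [
        nn.Flatten(),
        nn.Dense(flat, 512, rng), nn.BatchNorm(512), nn.ReLU(),
        nn.Identity("max-pool printed after the dense head; no-op on a vector"),
        nn.Dense(512, N_CLASSES, rng),
    ]
    return ClassifierModel("baseline", (w, h, 1), net := nn.Sequential(layers),
                           training_meta={"seed": seed, "epochs": 0})


# --- data plumbing ---------------------------------------------------------

def _to_arrays(
    dataset, model: ClassifierModel
) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of (BeatImage, class_index) pairs or an (X, y) tuple;
    return (N, 1, h, w) float32 in [0, 1] and int labels."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.max() > 1.0:
            X = X / 255.0
    else:
        grids, y = [], []
        for img, idx in dataset:
            _check_geometry(model, img)
            grids.append(img.grid)
            y.append(idx)
        X = np.asarray(grids, dtype=np.float32)[:, None, :, :] / 255.0
    y = np.asarray(y, dtype=np.int64)
    if X.shape[2:] != (model.height, model.width):
        raise ShapeError(
            f"images are {X.shape[3]}x{X.shape[2]} (w x h) but the "
            f"{model.architecture_id} network expects {model.width}x{model.height}"
        )
    return X, y


def _check_geometry(model: ClassifierModel, image: BeatImage) -> None:
    if (image.width, image.height) != (model.width, model.height):
        raise ShapeError(
            f"image is {image.width}x{image.height} (w x h) but the "
            f"{model.architecture_id} network expects {model.width}x{model.height}"
        )


def train(
    model: ClassifierModel,
    train_set,
    epochs: int,
    batch_size: int = 512,
    seed: int = 0,
    learning_rate: float = 1e-3,
) -> tuple[ClassifierModel, list[dict]]:
    """Train in place with Adam on categorical cross-entropy.

    Returns ``(model, log)`` where ``log`` has one entry per epoch with
    the mean minibatch loss and the training accuracy.  ``epochs=0``
    returns the model untouched with an empty log.
    """
    if epochs == 0:
        return model, []
    X, y = _to_arrays(train_set, model)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.network.params, lr=learning_rate)
    log: list[dict] = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), batch_size):
            idx = order[start : start + batch_size]
            logits = model.network.forward(X[idx], training=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, y[idx])
            model.network.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        log.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / len(X),
        })
    model.training_meta.update(
        epochs=model.training_meta.get("epochs", 0) + epochs,
        batch_size=batch_size, seed=seed,
    )
    return model, log


def predict(model: ClassifierModel, image: BeatImage) -> Prediction:
    """Classify one beat image."""
    _check_geometry(model, image)
    x = image.grid.astype(np.float32)[None, None, :, :] / 255.0
    probs = nn.softmax(model.network.forward(x, training=False))[0]
    k = int(probs.argmax())
    return Prediction(k, float(probs[k]), probs)


def predict_batch(
    model: ClassifierModel, images: Sequence[BeatImage], batch_size: int = 512
) -> list[Prediction]:
    """Classify many images; results are returned in input order."""
    out: list[Prediction] = []
    for img in images:
        _check_geometry(model, img)
    grids = np.asarray([img.grid for img in images], dtype=np.float32)
    X = grids[:, None, :, :] / 255.0
    for start in range(0, len(X), batch_size):
        probs = nn.softmax(model.network.forward(X[start : start + batch_size],
                                                 training=False))
        for p in probs:
            k = int(p.argmax())
            out.append(Prediction(k, float(p[k]), p))
    return out


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    """Serialize weights (npz) + metadata (json sidecar)."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, **model.network.state_arrays())
    meta = {
        "architecture_id": model.architecture_id,
        "input_shape": list(model.input_shape),
        "label_vocabulary": list(model.label_vocabulary),
        "training_meta": model.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    builder = {"proposed": build_proposed, "baseline": build_baseline}[
        meta["architecture_id"]
    ]
    model = builder()
    with np.load(path) as state:
        model.network.load_state_arrays(dict(state))
    model.training_meta = meta["training_meta"]
    return model


# --- Model / Results facade ------------------------------------------------

class BeatClassifier:
    """Model object: an architecture bound to a beat-image dataset.

    Parameters
    ----------
    train_set, test_set
        Lists of ``(BeatImage, class_index)`` pairs, e.g. from
        :func:`ecgvision.preprocess.build_dataset`.
    architecture
        ``"proposed"`` (180x64 input) or ``"baseline"`` (128x128).
    """

    def __init__(self, train_set, test_set=None, architecture: str = "proposed",
                 seed: int = 0):
        if architecture not in ("proposed", "baseline"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.architecture = architecture
        self.seed = seed
        self.train_set = train_set
        self.test_set = test_set or []

    def fit(self, epochs: int = 10, batch_size: int = 512,
            learning_rate: float = 1e-3) -> "TrainingResults":
        builder = {"proposed": build_proposed, "baseline": build_baseline}
        model = builder[self.architecture](seed=self.seed)
        model, log = train(model, self.train_set, epochs=epochs,
                           batch_size=batch_size, seed=self.seed,
                           learning_rate=learning_rate)
        return TrainingResults(model, log, self.test_set)


class TrainingResults:
    """Fit results: trained network, training history, test metrics."""

    def __init__(self, model: ClassifierModel, log: list[dict], test_set):
        self.model = model
        self.history = pd.DataFrame(log, columns=["epoch", "loss", "accuracy"])
        self.test_set = test_set
        self._test_metrics = None

    def predict(self, images: Sequence[BeatImage] | BeatImage):
        if isinstance(images, BeatImage):
            return predict(self.model, images)
        return predict_batch(self.model, images)

    def evaluate(self, dataset=None, average: str = "macro") -> dict:
        """Accuracy / precision / sensitivity / specificity on a dataset
        (defaults to the held-out test set)."""
        dataset = self.test_set if dataset is None else dataset
        if not dataset:
            raise ValueError("no test set to evaluate")
        images = [img for img, _ in dataset]
        truth = [CLASS_LABELS[idx] for _, idx in dataset]
        preds = [p.symbol for p in predict_batch(self.model, images)]
        cm = confusion(truth, preds)
        return summarize(cm, average=average)

    def summary(self) -> str:
        """Plain-text report: architecture, history, held-out metrics."""
        lines = [
            f"Beat classifier ({self.model.architecture_id})",
            f"  input geometry : {self.model.width} x {self.model.height} x 1",
            f"  parameters     : {self.model.num_params:,}",
            f"  classes        : {len(self.model.label_vocabulary)}",
            "",
            "Training history",
        ]
        lines += ["  " + ln for ln in self.history.to_string(index=False).splitlines()]
        if self.test_set:
            if self._test_metrics is None:
                self._test_metrics = self.evaluate()
            lines += ["", "Held-out metrics (macro one-vs-rest)"]
            for k, v in self._test_metrics.items():
                lines.append(f"  {k:<12}: {v:.3f}")
        return "\n".join(lines)
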