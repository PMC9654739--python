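"""Five-class olive quality classifier.

Olive crops are graded into the five veraison/defect classes
(Bad Black, Good Black, Bad Green, Good Green, Top Green).  The dataset is
randomly split 70/30 into training and test sets, and the network is trained
with stochastic gradient descent with momentum (SGDM), mini-batch 10, 10
epochs, reshuffling every epoch and keeping the partial final batch, so a
training set of 389 crops runs exactly 390 optimizer iterations.  The head is
a softmax producing a 5-component probability vector p; the predicted class
is the largest component (lowest index on ties).

The default backbone is a compact convolutional net (one 3x3 conv block plus
a dense hidden layer, 32x32 input) implemented directly on numpy so it trains
on a CPU in seconds.  Backbones are pluggable via a registry.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image

__all__ = [
    "CLASSES",
    "INPUT_SIZE",
    "LabeledDataset",
    "SplitSpec",
    "TrainConfig",
    "ClassProbability",
    "ConfusionMatrix",
    "Model",
    "TrainLog",
    "split_dataset",
    "planned_iterations",
    "train",
    "predict",
    "evaluate",
    "confusion",
    "preprocess_crop",
    "save_model",
    "load_model",
]

CLASSES = ("Bad Black", "Good Black", "Bad Green", "Good Green", "Top Green")
INPUT_SIZE = 32


@dataclass(frozen=True)
class LabeledDataset:
    """Labelled olive crops; labels drawn from the 5-class set."""

    items: tuple  # of (crop: HxWx3 uint8, label: str)

    def __post_init__(self) -> None:
        for _, label in self.items:
            if label not in CLASSES:
                raise ValueError(f"unknown label {label!r}")
        object.__setattr__(self, "items", tuple(self.items))

    def __len__(self) -> int:
        return len(self.items)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for _, label in self.items:
            counts[label] += 1
        return counts

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(tuple(self.items[i] for i in indices))

    @classmethod
    def from_manifest(cls, manifest_path) -> "LabeledDataset":
        """Load a ``crop_path,label`` CSV manifest (paths relative to it)."""
        import pandas as pd
        from pathlib import Path

        base = Path(manifest_path).parent
        df = pd.read_csv(manifest_path)
        items = []
        for _, row in df.iterrows():
            p = Path(row["crop_path"])
            if not p.is_absolute():
                p = base / p
            items.append((np.asarray(Image.open(p).convert("RGB")), row["label"]))
        return cls(tuple(items))


@dataclass
class SplitSpec:
    """Reproducible random train/test partition; |train| = floor(fraction*n)."""

    train_fraction: float = 0.7
    seed: int = 0
    train_indices: tuple = ()
    test_indices: tuple = ()


def split_dataset(ds: LabeledDataset, spec: SplitSpec):
    """Split a dataset by a uniform random permutation under ``spec.seed``."""
    if not (0.0 < spec.train_fraction <= 1.0):
        raise ValueError("train_fraction must lie in (0, 1]")
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    n_train = math.floor(spec.train_fraction * n)
    spec.train_indices = tuple(int(i) for i in perm[:n_train])
    spec.test_indices = tuple(int(i) for i in perm[n_train:])
    return ds.subset(spec.train_indices), ds.subset(spec.test_indices)


@dataclass(frozen=True)
class TrainConfig:
    """SGDM training options (mini-batch 10, 10 epochs, lr 1e-4 by default).

    The default learning rate suits fine-tuning a pretrained backbone; for the
    compact from-scratch net use :meth:`for_compact_net`, which raises it.
    """

    optimizer: str = "sgdm"
    momentum: float = 0.9
    mini_batch: int = 10
    epochs: int = 10
    initial_lr: float = 1e-4
    validation_frequency: int = 6
    shuffle_each_epoch: bool = True
    augmentation: bool = False
    backbone_id: str = "compact_cnn"

    def __post_init__(self) -> None:
        if self.mini_batch < 1:
            raise ValueError("mini_batch must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.augmentation:
            raise NotImplementedError("data augmentation is out of scope")

    @classmethod
    def for_compact_net(cls, **overrides) -> "TrainConfig":
        kwargs = {"initial_lr": 1e-2, "backbone_id": "compact_cnn"}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class ClassProbability:
    """The softmax head's 5-component probability vector p."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(CLASSES),) or p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("p must be 5 non-negative components summing to 1")
        object.__setattr__(self, "p", p)

    @property
    def predicted_label(self) -> str:
        return CLASSES[int(np.argmax(self.p))]


def planned_iterations(n_train: int, mini_batch: int, epochs: int) -> int:
    """Total optimizer iterations: epochs x ceil(n/batch), partial batch kept."""
    return epochs * math.ceil(n_train / mini_batch)


def preprocess_crop(crop: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Resize a crop to the backbone input: centre-pad to square with the
    crop's border colour, then bilinear resample; output floats in [-0.5, 0.5]."""
    arr = np.asarray(crop)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("crop must be H x W x 3")
    h, w = arr.shape[:2]
    border = np.concatenate([arr[0], arr[-1], arr[:, 0], arr[:, -1]], axis=0)
    pad_color = np.median(border, axis=0)
    side = max(h, w)
    canvas = np.empty((side, side, 3), dtype=np.uint8)
    canvas[:] = np.clip(np.rint(pad_color), 0, 255).astype(np.uint8)
    y0 = (side - h) // 2
    x0 = (side - w) // 2
    canvas[y0 : y0 + h, x0 : x0 + w] = arr
    img = Image.fromarray(canvas).resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=float) / 255.0 - 0.5


# --------------------------------------------------------------------------
# Compact convolutional backbone (numpy)
# --------------------------------------------------------------------------


class CompactConvNet:
    """3x3 conv (8 filters) -> ReLU -> 2x2 average pool -> dense 64 -> softmax 5."""

    backbone_id = "compact_cnn"
    n_filters = 8
    hidden = 64

    def __init__(self, rng: np.random.Generator):
        k = 3
        c = 3
        conv_out = INPUT_SIZE - k + 1          # 30
        pooled = conv_out // 2                 # 15
        self.flat_dim = pooled * pooled * self.n_filters
        self.params = {
            "W1": rng.normal(0.0, math.sqrt(2.0 / (k * k * c)), (k * k * c, self.n_filters)),
            "b1": np.zeros(self.n_filters),
            "W2": rng.normal(0.0, math.sqrt(2.0 / self.flat_dim), (self.flat_dim, self.hidden)),
            "b2": np.zeros(self.hidden),
            "W3": rng.normal(0.0, math.sqrt(2.0 / self.hidden), (self.hidden, len(CLASSES))),
            "b3": np.zeros(len(CLASSES)),
        }

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # x: (N, H, W, 3) -> (N*oh*ow, 27), patch layout (kh, kw, C)
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
        # win: (N, oh, ow, C, 3, 3) -> move C last inside the patch
        win = np.moveaxis(win, 3, 5)  # (N, oh, ow, 3, 3, C)
        n, oh, ow = win.shape[:3]
        return np.ascontiguousarray(win).reshape(n * oh * ow, 27), (n, oh, ow)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        cols, (n, oh, ow) = self._im2col(x)
        z1 = cols @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0).reshape(n, oh, ow, self.n_filters)
        ph, pw = oh // 2, ow // 2
        pooled = a1[:, : ph * 2, : pw * 2].reshape(n, ph, 2, pw, 2, self.n_filters).mean(axis=(2, 4))
        flat = pooled.reshape(n, self.flat_dim)
        z2 = flat @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        logits = a2 @ p["W3"] + p["b3"]
        if want_cache:
            return logits, (cols, z1, (n, oh, ow, ph, pw), flat, z2, a2)
        return logits

    def backward(self, cache, dlogits: np.ndarray) -> dict:
        p = self.params
        cols, z1, (n, oh, ow, ph, pw), flat, z2, a2 = cache
        grads = {}
        grads["W3"] = a2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dz2 = (dlogits @ p["W3"].T) * (z2 > 0)
        grads["W2"] = flat.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dpooled = (dz2 @ p["W2"].T).reshape(n, ph, pw, self.n_filters)
        da1 = np.repeat(np.repeat(dpooled, 2, axis=1), 2, axis=2) / 4.0
        full = np.zeros((n, oh, ow, self.n_filters))
        full[:, : ph * 2, : pw * 2] = da1
        dz1 = (full.reshape(-1, self.n_filters)) * (z1 > 0)
        grads["W1"] = cols.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads


BACKBONES = {"compact_cnn": CompactConvNet}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class Model:
    """A trained backbone plus its configuration and class order."""

    net: CompactConvNet
    config: TrainConfig
    classes: tuple = CLASSES

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        return _softmax(self.net.forward(crops))

    def predict(self, crop: np.ndarray):
        x = preprocess_crop(crop)[None]
        prob = ClassProbability(self.predict_proba(x)[0])
        return prob, prob.predicted_label


@dataclass
class TrainLog:
    """Loss and validation accuracy sampled along the optimizer trajectory."""

    entries: list = field(default_factory=list)
    total_iterations: int = 0

    def record(self, iteration: int, loss: float, val_accuracy: float | None) -> None:
        self.entries.append(
            {"iteration": iteration, "loss": float(loss), "val_accuracy": val_accuracy}
        )


def train(
    train_set: LabeledDataset,
    cfg: TrainConfig,
    seed: int = 0,
    val_set: LabeledDataset | None = None,
):
    """Train the backbone with SGDM under the mini-batch protocol.

    Runs ``epochs * ceil(n/mini_batch)`` iterations, reshuffling every epoch
    and keeping the partial final batch.  The validation set (never used for
    gradient updates) is scored every ``validation_frequency`` iterations.
    Returns ``(Model, TrainLog)``.
    """
    if cfg.optimizer != "sgdm":
        raise ValueError("only the SGDM optimizer is supported")
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    empty = [c for c, k in train_set.class_counts.items() if k == 0]
    if empty:
        warnings.warn(f"training set has no samples for: {', '.join(empty)}")

    rng = np.random.default_rng(seed)
    net = BACKBONES[cfg.backbone_id](rng)
    x = np.stack([preprocess_crop(crop) for crop, _ in train_set.items])
    y = np.array([CLASSES.index(label) for _, label in train_set.items])
    x_val = y_val = None
    if val_set is not None and len(val_set) > 0:
        x_val = np.stack([preprocess_crop(crop) for crop, _ in val_set.items])
        y_val = np.array([CLASSES.index(label) for _, label in val_set.items])

    n = len(train_set)
    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    log = TrainLog()
    iteration = 0
    total = planned_iterations(n, cfg.mini_batch, cfg.epochs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        for start in range(0, n, cfg.mini_batch):
            idx = order[start : start + cfg.mini_batch]
            logits, cache = net.forward(x[idx], want_cache=True)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12))
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            dlogits /= len(idx)
            grads = net.backward(cache, dlogits)
            for k in net.params:
                velocity[k] = cfg.momentum * velocity[k] - cfg.initial_lr * grads[k]
                net.params[k] += velocity[k]
            iteration += 1
            if iteration == 1 or iteration % cfg.validation_frequency == 0 or iteration == total:
                acc = None
                if x_val is not None:
                    acc = float(
                        np.mean(np.argmax(net.forward(x_val), axis=1) == y_val)
                    )
                log.record(iteration, loss, acc)
    log.total_iterations = iteration
    return Model(net=net, config=cfg), log


def predict(model: Model, crop: np.ndarray):
    """Classify one crop: returns ``(ClassProbability, predicted_label)``."""
    return model.predict(crop)


def evaluate(model: Model, ds: LabeledDataset):
    """Accuracy plus the true/predicted label lists for a dataset."""
    if len(ds) == 0:
        return float("nan"), [], []
    x = np.stack([preprocess_crop(crop) for crop, _ in ds.items])
    pred_idx = np.argmax(model.predict_proba(x), axis=1)
    true = [label for _, label in ds.items]
    pred = [CLASSES[i] for i in pred_idx]
    acc = float(np.mean([t == p for t, p in zip(true, pred)]))
    return acc, true, pred


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple = CLASSES

    @property
    def per_class_recall(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row * 100.0, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.tolist(),
            "per_class_recall": [
                None if np.isnan(r) else round(float(r), 1) for r in self.per_class_recall
            ],
        }


def confusion(true_labels, predicted_labels, classes=CLASSES) -> ConfusionMatrix:
    """Cross-tabulate true against predicted labels."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def save_model(model: Model, path) -> None:
    """Persist a model as a single .npz archive with its config embedded."""
    meta = json.dumps({"config": asdict(model.config), "classes": list(model.classes)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.net.params)


def load_model(path) -> Model:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = TrainConfig(**meta["config"])
        net = BACKBONES[cfg.backbone_id](np.random.default_rng(0))
        for k in net.params:
            net.params[k] = data[k]
    return Model(net=net, config=cfg, classes=tuple(meta["classes"]))
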