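"""Scalogram-image classification: a small reference CNN plus a backbone contract.

The reference CNN is the desk-scale vehicle for exercising the pipeline:
three blocks of (3x3 convolution -> ReLU -> 2x2 max pooling) with 8/16/32
channels, global average pooling, and one dense softmax layer.  It is
implemented directly on NumPy with a seeded initializer and an Adam/SGD
training loop, so training is fully reproducible on any CPU.

Large pretrained image backbones (AlexNet-, ResNet-50-style networks) are
supported through :func:`attach_backbone`: any callable mapping an image
batch to a feature matrix can be plugged in, its classification head is
replaced by a freshly initialized dense layer, and only that head is
trained (the extractor stays frozen, the usual transfer-learning recipe
when the backbone arrives as an opaque feature extractor).

Default hyperparameters: Adam, learning rate 1e-4, batch size 30, 15
epochs, validation every 18 iterations.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "ClassifierHandle",
    "ReferenceCNNClassifier",
    "build_reference_cnn",
    "attach_backbone",
    "train",
    "predict",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference recipe)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 30
    max_epochs: int = 15
    validation_frequency: int = 18
    seed: int = 0
    class_order: list[str] | None = None

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 0:
            raise ValueError(f"max_epochs must be >= 0, got {self.max_epochs}")
        if self.validation_frequency < 1:
            raise ValueError(
                f"validation_frequency must be >= 1, got {self.validation_frequency}"
            )


@dataclass
class TrainingHistory:
    """Per-evaluation training curve records."""

    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)  # percent
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)  # percent

    def __len__(self) -> int:
        return len(self.iterations)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.mean(np.log(np.maximum(probs[np.arange(len(y_idx)), y_idx], 1e-12))))


class _ReferenceCNN:
    """NumPy implementation of the 8/16/32 conv -> GAP -> dense network."""

    CHANNELS = (8, 16, 32)

    def __init__(self, input_size: tuple[int, int], n_classes: int, seed: int = 0):
        h, w = input_size
        if h < 32 or w < 32:
            raise ValueError(f"input size must be at least 32x32, got {input_size}")
        if n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {n_classes}")
        self.input_size = (h, w)
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(self.CHANNELS):
            # He-normal initialization for ReLU layers
            std = np.sqrt(2.0 / (9 * c_in))
            self.params[f"W{i}"] = rng.normal(0, std, (3, 3, c_in, c_out)).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        std = np.sqrt(2.0 / c_in)
        self.params["Wd"] = rng.normal(0, std, (c_in, n_classes)).astype(np.float32)
        self.params["bd"] = np.zeros(n_classes, dtype=np.float32)

    @staticmethod
    def _conv_forward(x, W, b):
        # valid 3x3 convolution as nine shifted matmuls
        n, h, w, _ = x.shape
        ho, wo = h - 2, w - 2
        f = W.shape[-1]
        y = np.broadcast_to(b, (n, ho, wo, f)).copy()
        for di in range(3):
            for dj in range(3):
                y += x[:, di : di + ho, dj : dj + wo, :] @ W[di, dj]
        return y

    @staticmethod
    def _conv_backward(x, W, dy):
        n, h, w, _ = x.shape
        ho, wo = dy.shape[1], dy.shape[2]
        dW = np.empty_like(W)
        dx = np.zeros_like(x)
        for di in range(3):
            for dj in range(3):
                patch = x[:, di : di + ho, dj : dj + wo, :]
                dW[di, dj] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, di : di + ho, dj : dj + wo, :] += dy @ W[di, dj].T
        db = dy.sum(axis=(0, 1, 2))
        return dx, dW, db

    @staticmethod
    def _pool_forward(x):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : 2 * ho, : 2 * wo, :].reshape(n, ho, 2, wo, 2, c)
        y = xc.max(axis=(2, 4))
        return y, xc

    @staticmethod
    def _pool_backward(xc, y, dy):
        mask = xc == y[:, :, None, :, None, :]
        dxc = mask * dy[:, :, None, :, None, :]
        n, ho, _, wo, _, c = xc.shape
        return dxc.reshape(n, 2 * ho, 2 * wo, c)

    def forward(self, x: np.ndarray, with_cache: bool = False):
        """x: (n, H, W, 3) float32, standardized; returns logits."""
        cache = {"x0": x}
        a = x
        for i in range(3):
            z = self._conv_forward(a, self.params[f"W{i}"], self.params[f"b{i}"])
            r = np.maximum(z, 0)
            a, xc = self._pool_forward(r)
            cache[f"z{i}"], cache[f"xc{i}"], cache[f"a{i}"] = z, xc, a
        gap = a.mean(axis=(1, 2))
        cache["gap"] = gap
        logits = gap @ self.params["Wd"] + self.params["bd"]
        return (logits, cache) if with_cache else logits

    def backward(self, cache, dlogits):
        grads = {}
        gap = cache["gap"]
        grads["Wd"] = gap.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        da = dlogits @ self.params["Wd"].T
        a3 = cache["a2"]
        n, ho, wo, c = a3.shape
        da = np.broadcast_to(da[:, None, None, :] / (ho * wo), a3.shape).astype(np.float32)
        for i in range(2, -1, -1):
            dr = self._pool_backward(cache[f"xc{i}"], cache[f"a{i}"], da)
            z = cache[f"z{i}"]
            if dr.shape != z.shape:  # odd rows/cols cropped by the 2x2 pool
                pad = np.zeros_like(z)
                pad[:, : dr.shape[1], : dr.shape[2], :] = dr
                dr = pad
            dz = dr * (z > 0)
            x_prev = cache["x0"] if i == 0 else cache[f"a{i - 1}"]
            dx, dW, db = self._conv_backward(x_prev, self.params[f"W{i}"], dz)
            grads[f"W{i}"], grads[f"b{i}"] = dW, db
            da = dx
        return grads

    trainable = property(lambda self: list(self.params))


class _BackboneHead:
    """Frozen feature extractor + freshly initialized dense softmax head."""

    def __init__(self, extractor, n_classes: int, input_size: tuple[int, int], seed: int = 0):
        if n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {n_classes}")
        self.extractor = extractor
        self.input_size = tuple(input_size)
        self.n_classes = n_classes
        h, w = self.input_size
        probe = np.zeros((1, h, w, 3), dtype=np.float32)
        try:
            feats = np.asarray(extractor(probe))
        except Exception as exc:
            raise ValueError(
                f"feature extractor rejected a {h}x{w}x3 probe batch: {exc}"
            ) from exc
        if feats.ndim != 2 or feats.shape[0] != 1:
            raise ValueError(
                f"feature extractor must map (n, H, W, 3) to (n, d); probe gave "
                f"shape {feats.shape}"
            )
        d = feats.shape[1]
        rng = np.random.default_rng(seed)
        self.params = {
            "Wd": rng.normal(0, np.sqrt(2.0 / d), (d, n_classes)).astype(np.float32),
            "bd": np.zeros(n_classes, dtype=np.float32),
        }

    def forward(self, x, with_cache: bool = False):
        feats = np.asarray(self.extractor(x), dtype=np.float32)
        logits = feats @ self.params["Wd"] + self.params["bd"]
        return (logits, {"feats": feats}) if with_cache else logits

    def backward(self, cache, dlogits):
        return {"Wd": cache["feats"].T @ dlogits, "bd": dlogits.sum(axis=0)}


@dataclass
class ClassifierHandle:
    """Opaque trained-model reference plus its label order and input size.

    ``norm_mean``/``norm_std`` hold the per-channel standardization
    statistics computed from the training images (the usual image-pipeline
    preprocessing); they are applied identically at prediction time.
    """

    model: object
    class_order: list[str] | None
    input_size: tuple[int, int]
    provenance: str = "reference-cnn"
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None


def build_reference_cnn(
    input_size: tuple[int, int] = (227, 227), n_classes: int = 3, seed: int = 0
) -> ClassifierHandle:
    """Construct the untrained reference CNN (seeded initialization)."""
    return ClassifierHandle(
        model=_ReferenceCNN(input_size, n_classes, seed=seed),
        class_order=None,
        input_size=tuple(input_size),
        provenance=f"reference-cnn(seed={seed})",
    )


def attach_backbone(
    feature_extractor,
    n_classes: int,
    input_size: tuple[int, int] = (227, 227),
    seed: int = 0,
) -> ClassifierHandle:
    """Wrap an external image->features component with a fresh softmax head.

    The extractor is any callable mapping an (n, H, W, 3) batch to an (n, d)
    feature matrix; its original classification layer plays no role — a new
    ``d -> n_classes`` dense layer is initialized from the seed and is the
    only part trained.
    """
    if callable(getattr(feature_extractor, "extractor", None)):
        feature_extractor = feature_extractor.extractor  # re-wrap: idempotent head
    model = _BackboneHead(feature_extractor, n_classes, input_size, seed=seed)
    return ClassifierHandle(
        model=model,
        class_order=None,
        input_size=tuple(input_size),
        provenance="external-backbone",
    )


def _prepare_images(images: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValueError(f"images must be (n, H, W, 3), got shape {x.shape}")
    if x.shape[1:3] != tuple(input_size):
        raise ValueError(
            f"image size {x.shape[1:3]} does not match classifier input size "
            f"{tuple(input_size)}"
        )
    x = x.astype(np.float32)
    if x.max() > 1.5:  # uint8-scale input
        x = x / 255.0
    return x


def _standardize(x: np.ndarray, handle: ClassifierHandle) -> np.ndarray:
    if handle.norm_mean is None:
        return x - np.float32(0.5)
    return (x - handle.norm_mean) / handle.norm_std


def _evaluate(model, x, y_idx, batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch])
        probs = _softmax(logits)
        losses.append(_cross_entropy(probs, y_idx[i : i + batch]) * len(logits))
        correct += int((np.argmax(probs, axis=1) == y_idx[i : i + batch]).sum())
    return sum(losses) / len(x), 100.0 * correct / len(x)


def train(
    handle: ClassifierHandle,
    images,
    labels,
    val_images=None,
    val_labels=None,
    config: TrainConfig | None = None,
) -> tuple[ClassifierHandle, TrainingHistory]:
    """Train a classifier handle by mini-batch cross-entropy minimization.

    Shuffling and (for Adam) moment states are fully determined by
    ``config.seed``.  The history records training-batch and validation
    metrics every ``validation_frequency`` iterations and at the final
    iteration.  ``max_epochs=0`` returns the handle untouched with an empty
    history.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("training set is empty")
    class_order = list(config.class_order or handle.class_order or sorted(set(labels)))
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    handle.class_order = class_order
    if getattr(handle.model, "n_classes", len(class_order)) != len(class_order):
        raise ValueError(
            f"model has {handle.model.n_classes} outputs but class_order lists "
            f"{len(class_order)} classes"
        )

    history = TrainingHistory()
    if config.max_epochs == 0:
        return handle, history

    x = _prepare_images(images, handle.input_size)
    # per-channel standardization by training statistics; reused at predict time
    handle.norm_mean = x.mean(axis=(0, 1, 2), dtype=np.float64).astype(np.float32)
    handle.norm_std = np.maximum(
        x.std(axis=(0, 1, 2), dtype=np.float64).astype(np.float32), np.float32(1e-6)
    )
    x = _standardize(x, handle)
    lab_to_idx = {lab: i for i, lab in enumerate(class_order)}
    y_idx = np.array([lab_to_idx[l] for l in labels])
    have_val = val_images is not None and val_labels is not None
    if have_val:
        xv = _standardize(_prepare_images(val_images, handle.input_size), handle)
        yv = np.array([lab_to_idx[l] for l in np.asarray(val_labels)])

    model = handle.model
    rng = np.random.default_rng(config.seed)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    t_step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    it = 0
    n = len(x)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y_idx[idx]
            logits, cache = model.forward(xb, with_cache=True)
            probs = _softmax(logits)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(np.float32)
            grads = model.backward(cache, dlogits)

            t_step += 1
            for k, g in grads.items():
                if config.optimizer == "adam":
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    mhat = adam_m[k] / (1 - beta1**t_step)
                    vhat = adam_v[k] / (1 - beta2**t_step)
                    model.params[k] -= (
                        config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    ).astype(np.float32)
                else:
                    model.params[k] -= (config.learning_rate * g).astype(np.float32)

            it += 1
            is_last = _epoch == config.max_epochs - 1 and start + config.batch_size >= n
            if it % config.validation_frequency == 0 or is_last:
                batch_loss = _cross_entropy(probs, yb)
                batch_acc = 100.0 * float(np.mean(np.argmax(probs, axis=1) == yb))
                history.iterations.append(it)
                history.train_loss.append(batch_loss)
                history.train_accuracy.append(batch_acc)
                if have_val:
                    vl, va = _evaluate(model, xv, yv)
                else:
                    vl, va = float("nan"), float("nan")
                history.val_loss.append(vl)
                history.val_accuracy.append(va)

    return handle, history


def predict(handle: ClassifierHandle, images, batch: int = 64):
    """Predict labels and class probabilities for an image batch.

    The label is the argmax probability; exact ties resolve to the earliest
    class in ``class_order``.
    """
    if handle.class_order is None:
        raise ValueError("handle has no class_order; train it or set class_order first")
    x = _standardize(_prepare_images(images, handle.input_size), handle)
    probs = np.concatenate(
        [_softmax(handle.model.forward(x[i : i + batch])) for i in range(0, len(x), batch)]
    )
    idx = np.argmax(probs, axis=1)  # first-max tie break = earliest class
    labels = np.array([handle.class_order[i] for i in idx])
    return labels, probs


def save_handle(handle: ClassifierHandle, path) -> None:
    """Persist a trained handle (reference CNN only) to disk."""
    with open(Path(path), "wb") as fh:
        pickle.dump(handle, fh)


def load_handle(path) -> ClassifierHandle:
    with open(Path(path), "rb") as fh:
        return pickle.load(fh)


class ReferenceCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the reference CNN.

    ``fit`` expects ``X`` as an (n, H, W, 3) uint8 image stack and ``y`` as
    string or integer labels; ``predict`` returns labels from ``classes_``
    with exact argmax ties resolved toward the earliest class.

    Parameters mirror :class:`TrainConfig`; ``random_state`` seeds both the
    weight initialization and the batch shuffling.

    Attributes
    ----------
    classes_ : numpy.ndarray
        Label order (columns of ``predict_proba``).
    history_ : TrainingHistory
        Training curve recorded during ``fit``.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (227, 227),
        optimizer: str = "adam",
        learning_rate: float = 1e-4,
        batch_size: int = 30,
        max_epochs: int = 15,
        validation_frequency: int = 18,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_frequency = validation_frequency
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        y = np.asarray(y)
        classes = sorted(set(y.tolist()))
        handle = build_reference_cnn(
            input_size=self.input_size, n_classes=len(classes), seed=self.random_state
        )
        cfg = TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            validation_frequency=self.validation_frequency,
            seed=self.random_state,
            class_order=classes,
        )
        val_X, val_y = validation_data if validation_data is not None else (None, None)
        handle, history = train(handle, X, y, val_X, val_y, cfg)
        self.handle_ = handle
        self.history_ = history
        self.classes_ = np.asarray(classes)
        return self

    def predict(self, X):
        labels, _ = predict(self.handle_, X)
        return labels

    def predict_proba(self, X):
        _, probs = predict(self.handle_, X)
        return probs
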