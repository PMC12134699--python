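"""The confounding-resilient smoking (CRS) gesture classifier.

A compact CNN over 200×6 sensor windows (200 time points × [linear
acceleration x,y,z, gyro x,y,z]).  The window is treated as a
single-channel 2D grid so kernels span time and sensor axes jointly:

    conv 8 @ 5×5  (leaky ReLU)
    conv 16 @ 3×3 (leaky ReLU)
    maxpool 2×1
    conv 32 @ 3×3 (leaky ReLU)
    maxpool 2×1
    flatten → dense 1024 (leaky ReLU) → dropout 0.5
    dense n_classes → softmax

All convolutions use "same" padding (a 5×5 kernel would otherwise
nearly exhaust the 6-wide sensor axis), so the flattened feature map is
50×6×32 = 9600.  Training uses categorical cross-entropy with Adam at
learning rate 0.001, batch size 32.  The same architecture serves the
2-class (smoking vs non-smoking) and 16-class (per-gesture) problems,
differing only in output width.

Windows are z-scored per channel with statistics fit on the training
set only; the statistics are stored on the model and applied at
inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .gestures import GESTURE_NAMES, SMOKING_CLASS, GestureRecording
from .preprocess import process_recording_array

__all__ = [
    "SensorWindow",
    "ModelConfig",
    "TrainConfig",
    "CrsModel",
    "build_model",
    "predict_proba",
    "train",
    "classify",
    "parameter_count",
    "windows_from_recordings",
    "window_from_recording",
    "CnnClassifier",
    "save_model",
    "load_model",
]

WINDOW_LEN = 200
N_CHANNELS = 6

CHECKPOINT_VERSION = "crsdetect-ckpt-1"


@dataclass(frozen=True)
class SensorWindow:
    """One fixed 200×6 classifier input."""

    values: np.ndarray
    label: int | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        _check_window(v)
        object.__setattr__(self, "values", v)


def _check_window(v: np.ndarray) -> None:
    if v.shape != (WINDOW_LEN, N_CHANNELS):
        raise ValueError(
            f"window must be {WINDOW_LEN}x{N_CHANNELS} "
            f"(time points x sensor channels), got {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("window values must be finite")


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 2
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    kernel_sizes: tuple[tuple[int, int], ...] = ((5, 5), (3, 3), (3, 3))
    dense_units: int = 1024
    dropout: float = 0.5
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    loss: str = "categorical_crossentropy"
    seed: int = 0
    optimizer_name: str = "adam"

    def __post_init__(self) -> None:
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class CrsModel:
    """Classifier handle: layers, config, normalization stats, RNG."""

    config: ModelConfig
    layers: list
    seed: int
    rng: np.random.Generator
    norm_mean: np.ndarray | None = None  # (6,)
    norm_std: np.ndarray | None = None  # (6,)
    history: list = field(default_factory=list)

    def layer_shapes(self) -> list[tuple]:
        """Report output shape after each stage for a single window."""
        x = np.zeros((1, WINDOW_LEN, N_CHANNELS, 1), dtype=np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes.append(tuple(x.shape[1:]))
        return shapes


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> CrsModel:
    """Instantiate the network with seeded weight initialization."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    f1, f2, f3 = config.conv_filters
    (k1h, k1w), (k2h, k2w), (k3h, k3w) = config.kernel_sizes
    slope = config.leaky_slope
    flat_dim = (WINDOW_LEN // 4) * N_CHANNELS * f3
    layers = [
        nn.Conv2D(1, f1, k1h, k1w, rng),
        nn.LeakyReLU(slope),
        nn.Conv2D(f1, f2, k2h, k2w, rng),
        nn.LeakyReLU(slope),
        nn.MaxPool2x1(),
        nn.Conv2D(f2, f3, k3h, k3w, rng),
        nn.LeakyReLU(slope),
        nn.MaxPool2x1(),
        nn.Flatten(),
        nn.Dense(flat_dim, config.dense_units, rng),
        nn.LeakyReLU(slope),
        nn.Dropout(config.dropout, rng),
        nn.Dense(config.dense_units, config.n_classes, rng),
    ]
    return CrsModel(config=config, layers=layers, seed=int(seed), rng=rng)


def parameter_count(model: CrsModel) -> int:
    return sum(getattr(l, "n_params", 0) for l in model.layers)


def _prepare_batch(model: CrsModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if model.norm_mean is not None:
        x = (x - model.norm_mean) / model.norm_std
    return x[..., None]  # (B, 200, 6, 1)


def _forward(model: CrsModel, x: np.ndarray, train: bool) -> np.ndarray:
    for layer in model.layers:
        x = layer.forward(x, train=train)
    return x


def predict_proba(model: CrsModel, window) -> np.ndarray:
    """Class-probability vector(s); dropout inactive, deterministic.

    Accepts a single SensorWindow / 200×6 array (returns shape
    ``(n_classes,)``) or a stack of windows (returns ``(n, n_classes)``).
    """
    if isinstance(window, SensorWindow):
        v = window.values
    else:
        v = np.asarray(window, dtype=np.float32)
    single = v.ndim == 2
    if single:
        _check_window(v)
        v = v[None]
    elif v.ndim != 3 or v.shape[1:] != (WINDOW_LEN, N_CHANNELS):
        raise ValueError(
            f"expected (n, {WINDOW_LEN}, {N_CHANNELS}) window stack, got {v.shape}"
        )
    out = []
    for start in range(0, v.shape[0], 256):
        logits = _forward(model, _prepare_batch(model, v[start : start + 256]), train=False)
        out.append(nn.softmax(logits.astype(np.float64)))
    p = np.concatenate(out, axis=0)
    return p[0] if single else p


def classify(model: CrsModel, window) -> tuple[int, float]:
    """Argmax label and its probability; ties break to the lowest index."""
    p = predict_proba(model, window)
    if p.ndim != 1:
        raise ValueError("classify takes a single window; use predict_proba for batches")
    label = int(np.argmax(p))  # argmax returns the first maximum → lowest index on ties
    return label, float(p[label])


def train(
    model: CrsModel,
    windows: np.ndarray | Sequence[SensorWindow],
    labels: Sequence[int] | None = None,
    tc: TrainConfig = TrainConfig(),
) -> list[dict]:
    """Train in place; returns (and stores) the per-epoch history.

    ``windows`` is either an (n, 200, 6) array with ``labels``, or a
    sequence of labelled SensorWindows.  Normalization statistics are
    fit here, on the training data only, if not already present.
    """
    if labels is None:
        ws = list(windows)
        if any(w.label is None for w in ws):
            raise ValueError("all windows must carry labels")
        x = np.stack([w.values for w in ws])
        y = np.array([w.label for w in ws], dtype=int)
    else:
        x = np.asarray(windows, dtype=np.float32)
        y = np.asarray(labels, dtype=int)
    if x.ndim != 3 or x.shape[1:] != (WINDOW_LEN, N_CHANNELS):
        raise ValueError(f"expected (n, {WINDOW_LEN}, {N_CHANNELS}) windows, got {x.shape}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training data must contain >= 2 classes, got {classes.size}")
    if y.min() < 0 or y.max() >= model.config.n_classes:
        raise ValueError("labels out of range for the model's n_classes")

    if model.norm_mean is None:
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        std[std < 1e-8] = 1.0
        model.norm_mean = mean.astype(np.float32)
        model.norm_std = std.astype(np.float32)

    if tc.epochs == 0:
        return []

    onehot_all = np.eye(model.config.n_classes, dtype=np.float32)[y]
    opt = nn.Adam(model.layers, lr=tc.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(tc.seed), 13]))
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(tc.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = _prepare_batch(model, x[idx])
            logits = _forward(model, xb, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, onehot_all[idx])
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    model.history.extend(history)
    return history


# ---------------------------------------------------------------------------
# window assembly from recordings

def window_from_recording(
    recording: GestureRecording,
    alpha: float = 0.8,
    repeats: int = 2,
) -> np.ndarray:
    """Build one 200×6 window from a trial.

    The trial's raw acceleration is gravity-filtered, concatenated with
    the gyro channels, then tiled ``repeats`` times (a 5 s trial at
    20 Hz yields 100 samples, so 2 repeats fill the 200-sample model
    input) and truncated/cycled to exactly 200 rows.
    """
    linear = process_recording_array(recording.accel, alpha=alpha)
    chans = np.concatenate([linear, recording.gyro], axis=1).astype(np.float32)
    tiled = np.tile(chans, (max(int(repeats), 1), 1))
    while tiled.shape[0] < WINDOW_LEN:
        tiled = np.concatenate([tiled, chans], axis=0)
    return tiled[:WINDOW_LEN]


def windows_from_recordings(
    recordings: Sequence[GestureRecording],
    alpha: float = 0.8,
    repeats: int = 2,
    binary: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Vectorize a recording set into (X, y, participant_ids, class_names).

    ``binary=True`` labels smoking=1 / non-smoking=0; otherwise labels
    index the 16 activity names in protocol order.
    """
    xs, ys, pids = [], [], []
    names = list(GESTURE_NAMES)
    for rec in recordings:
        xs.append(window_from_recording(rec, alpha=alpha, repeats=repeats))
        if binary:
            ys.append(1 if rec.activity == SMOKING_CLASS else 0)
        else:
            ys.append(names.index(rec.activity))
        pids.append(rec.participant_id)
    class_names = ["non_smoking", SMOKING_CLASS] if binary else names
    return np.stack(xs), np.asarray(ys, dtype=int), pids, class_names


# ---------------------------------------------------------------------------
# sklearn-style adapter (used by LOSO and the CLI)

class CnnClassifier:
    """fit/predict wrapper so evaluation code can treat the CNN generically."""

    def __init__(
        self,
        n_classes: int = 2,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 0.001,
        seed: int = 0,
    ):
        self.model_config = ModelConfig(n_classes=n_classes)
        self.train_config = TrainConfig(
            learning_rate=learning_rate, epochs=epochs, batch_size=batch_size, seed=seed
        )
        self.seed = seed
        self.model: CrsModel | None = None

    def fit(self, x: np.ndarray, y: Sequence[int]) -> "CnnClassifier":
        self.model = build_model(self.model_config, seed=self.seed)
        train(self.model, x, y, self.train_config)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        p = predict_proba(self.model, x)
        return p[None] if p.ndim == 1 else p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: CrsModel, path: str | Path) -> None:
    """Persist weights + config + normalization stats to one .npz file."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.params):
            arrays[f"param_{i}_{j}"] = p
    meta = {
        "version": CHECKPOINT_VERSION,
        "seed": model.seed,
        "config": {
            "n_classes": model.config.n_classes,
            "conv_filters": list(model.config.conv_filters),
            "kernel_sizes": [list(k) for k in model.config.kernel_sizes],
            "dense_units": model.config.dense_units,
            "dropout": model.config.dropout,
            "leaky_slope": model.config.leaky_slope,
        },
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if model.norm_mean is not None:
        arrays["norm_mean"] = model.norm_mean
        arrays["norm_std"] = model.norm_std
    np.savez(path, **arrays)


def load_model(path: str | Path) -> CrsModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']!r}")
        cfg = meta["config"]
        config = ModelConfig(
            n_classes=cfg["n_classes"],
            conv_filters=tuple(cfg["conv_filters"]),
            kernel_sizes=tuple(tuple(k) for k in cfg["kernel_sizes"]),
            dense_units=cfg["dense_units"],
            dropout=cfg["dropout"],
            leaky_slope=cfg["leaky_slope"],
        )
        model = build_model(config, seed=meta["seed"])
        for i, layer in enumerate(model.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"param_{i}_{j}"]
        if "norm_mean" in data:
            model.norm_mean = data["norm_mean"]
            model.norm_std = data["norm_std"]
    return model
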