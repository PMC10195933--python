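"""Positioning-feature classifiers and landmark regressors.

The architecture is a VGG-style network: 13 convolutional layers with 3x3
kernels in the canonical 2-2-3-3-3 grouping with five max-pooling layers
in between, batch normalisation after every convolution, two dense ReLU
layers, and 50% dropout before the output head.  Classification uses a
softmax head with (class-weighted) cross-entropy; landmark regression
uses a sigmoid head over normalised coordinates with mean-squared-error
loss.  Optimisation is stochastic gradient descent; one checkpoint metric
is recorded per epoch and the epoch with the highest validation accuracy
(classification) or lowest validation RMSE (regression) is selected.

Defaults reproduce the full-scale training recipe (224 px input, width
multiplier 1.0, batches of 32, learning rate 1e-5, 160 epochs).  A
scaled-down profile (96 px input, width multiplier 0.25, 30 epochs,
momentum SGD at lr 0.01) is a first-class configuration used for
desk-scale experiments on phantoms; it is the same code path, not a fork.

Two sklearn-style estimators wrap the engine: ``PositioningClassifier``
and ``LandmarkRegressor`` (fit/predict, ``get_params``/``set_params``,
fitted attributes with a trailing underscore); the module-level functions
(`build_network`, `class_weights`, `augment`, `split_train_val`,
`train_network`, `predict_class`, `predict_landmark`) are the thin
functional surface over the same machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .preprocess import TransformLog

#: channel widths of the canonical 13-conv/5-pool topology
_BASE_WIDTHS = [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]
_CONV_GROUPS = [2, 2, 3, 3, 3]
_BASE_DENSE = 512


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters.

    The defaults are the full-scale recipe; pass ``input_side_px=96,
    width_multiplier=0.25, epochs=30, lr=0.01, momentum=0.9`` (or use
    :func:`scaled_down_config`) for the desk-scale profile.
    """

    task: str = "classification"
    input_side_px: int = 224
    conv_layers: int = 13
    kernel: Tuple[int, int] = (3, 3)
    pool_layers: int = 5
    dense_layers: int = 2
    dropout: float = 0.5
    width_multiplier: float = 1.0
    n_classes: int = 2
    n_coords: int = 2
    lr: float = 1.0e-5
    momentum: float = 0.0
    batch_size: int = 32
    epochs: int = 160
    val_fraction: float = 0.25  # the 3:1 train/validation split
    augment_rotation_deg: float = 10.0
    augment_shift_frac: float = 0.05
    augment_zoom_frac: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be classification or regression")
        if self.conv_layers != 13 or self.pool_layers != 5 or self.dense_layers != 2:
            raise ValueError("the topology is fixed at 13 conv / 5 pool / 2 dense")
        if tuple(self.kernel) != (3, 3):
            raise ValueError("kernel is fixed at 3x3")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.input_side_px % 2 ** self.pool_layers != 0:
            raise ValueError(
                f"input_side_px must be divisible by {2 ** self.pool_layers}"
            )
        if self.input_side_px < 2 ** self.pool_layers:
            raise ValueError("input too small for the pooling depth")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = list(d["kernel"])
        return d


def scaled_down_config(task: str = "classification", seed: int = 0, **kw) -> ModelConfig:
    """Desk-scale profile: 96 px input, width 0.25, 30 epochs, momentum SGD."""
    base = dict(task=task, input_side_px=96, width_multiplier=0.25,
                epochs=30, lr=0.01, momentum=0.9, seed=seed)
    base.update(kw)
    return ModelConfig(**base)


def build_network(cfg: ModelConfig) -> nn.Network:
    """Instantiate the (untrained) network for a config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    widths = [max(1, int(round(w * cfg.width_multiplier))) for w in _BASE_WIDTHS]
    layers: List[nn.Layer] = []
    c_in, i = 1, 0
    side = cfg.input_side_px
    for group in _CONV_GROUPS:
        for _ in range(group):
            layers.append(nn.Conv3x3(c_in, widths[i], rng, is_input=not layers))
            layers.append(nn.BatchNorm2d(widths[i]))
            layers.append(nn.ReLU())
            c_in = widths[i]
            i += 1
        layers.append(nn.MaxPool2x2())
        side //= 2
    layers.append(nn.Flatten())
    n_flat = side * side * c_in
    n_dense = max(4, int(round(_BASE_DENSE * cfg.width_multiplier)))
    for _ in range(cfg.dense_layers):
        layers.append(nn.Dense(n_flat, n_dense, rng))
        layers.append(nn.ReLU())
        n_flat = n_dense
    layers.append(nn.Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 1)))
    if cfg.task == "classification":
        layers.append(nn.Dense(n_flat, cfg.n_classes, rng))
        head = nn.SoftmaxCrossEntropy()
    else:
        layers.append(nn.Dense(n_flat, cfg.n_coords, rng))
        head = nn.SigmoidMSE()
    return nn.Network(layers, head)


def class_weights(labels: Sequence[int]) -> Dict[int, float]:
    """Inverse-frequency class weights w_c = N / (K * N_c).

    Balanced labels give weight 1.0 for every class; a single-class input
    is rejected (weighting is meaningless and training would be too).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to weight")
    n, k = labels.size, len(classes)
    return {int(c): float(n / (k * m)) for c, m in zip(classes, counts)}


def augment(
    images: np.ndarray,
    coords: Optional[np.ndarray],
    rotation_deg: float,
    shift_frac: float,
    zoom_frac: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Random rotation / shift / zoom of a batch, with consistent targets.

    ``images`` is (n, side, side); ``coords`` (optional) is (n, 2) pixel
    coordinates (x, y) that receive the same geometric transform as their
    image.  Zero ranges return the batch unchanged.  Deterministic under
    ``rng``.
    """
    if rotation_deg == 0 and shift_frac == 0 and zoom_frac == 0:
        return images, coords
    n, side = images.shape[0], images.shape[1]
    out = np.empty_like(images)
    out_c = None if coords is None else np.empty_like(coords)
    c = (side - 1) / 2.0
    for i in range(n):
        theta = np.radians(rng.uniform(-rotation_deg, rotation_deg))
        zoom = 1.0 + rng.uniform(-zoom_frac, zoom_frac)
        dx = rng.uniform(-shift_frac, shift_frac) * side
        dy = rng.uniform(-shift_frac, shift_frac) * side
        # forward map (row, col): p' = z*R(theta) (p - c) + c + d
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]]) * zoom
        Rinv = np.linalg.inv(R)
        offset = np.array([c, c]) - Rinv @ (np.array([c, c]) + np.array([dy, dx]))
        out[i] = ndimage.affine_transform(
            images[i], Rinv, offset=offset, order=1, mode="constant", cval=0.0
        )
        if coords is not None:
            x, y = coords[i]
            ry, rx = R @ (np.array([y, x]) - c) + c + np.array([dy, dx])
            out_c[i] = (rx, ry)
    return out, out_c


def split_train_val(
    X, y, ratio: float = 0.25, seed: int = 0, stratify: bool = True
):
    """Random (optionally stratified) split; default 3:1 train:validation."""
    strat = y if (stratify and np.asarray(y).ndim == 1) else None
    return train_test_split(X, y, test_size=ratio, random_state=seed, stratify=strat)


@dataclass
class TrainedModel:
    """A trained network plus its config, history and selected checkpoint."""

    network: nn.Network
    config: ModelConfig
    history: pd.DataFrame
    selected_epoch: int


@dataclass
class Prediction:
    """One model output: class probabilities or normalised coordinates."""

    probabilities: Optional[np.ndarray] = None
    coords_norm: Optional[np.ndarray] = None

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probabilities))


def _epoch_metric(net, head_task, Xv, yv, side, batch_size=32):
    # evaluate at the training batch size so conv work buffers are reused
    p = net.predict(Xv, batch_size=batch_size)
    if head_task == "classification":
        return float((p.argmax(axis=1) == yv).mean())
    # RMSE in model-frame pixels
    d = (p - yv) * side
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


def train_network(
    net: nn.Network,
    train_data: Tuple[np.ndarray, np.ndarray],
    val_data: Tuple[np.ndarray, np.ndarray],
    cfg: ModelConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Run the training loop; returns the best-checkpoint model.

    ``train_data``/``val_data`` are ``(X, y)`` with X of shape
    (n, side, side) in [0, 1]; classification y are int labels, regression
    y are normalised coordinates in [0, 1]^2 (x, y order).

    Augmentation (rotation/shift/zoom) is re-drawn every epoch; class
    weights counteract imbalance; one validation metric is recorded per
    epoch and the weights of the best epoch (ties -> earliest) are
    restored before returning.
    """
    cfg.validate()
    Xt, yt = train_data
    Xv, yv = val_data
    if len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1000)
    opt = nn.SGD(cfg.lr, cfg.momentum)
    side = cfg.input_side_px

    is_clf = cfg.task == "classification"
    if is_clf:
        weights = class_weights(yt) if len(np.unique(yt)) > 1 else {int(yt[0]): 1.0}
        sw_all = np.array([weights[int(c)] for c in yt], dtype=np.float64)
        yt = np.asarray(yt, dtype=np.int64)
        coords_px = None
    else:
        yt = np.asarray(yt, dtype=np.float64)
        sw_all = None
        coords_px = yt * side  # normalised -> model-frame pixels

    hist, best_metric, best_epoch, best_weights = [], None, -1, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xt))
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Xt[idx]
            cb = None if coords_px is None else coords_px[idx]
            xb, cb = augment(xb, cb, cfg.augment_rotation_deg,
                             cfg.augment_shift_frac, cfg.augment_zoom_frac, rng)
            xb = xb[..., None]  # NHWC
            if is_clf:
                loss = net.train_step(xb, yt[idx], opt, sw_all[idx])
            else:
                tb = np.clip(cb / side, 0.0, 1.0)
                loss = net.train_step(xb, tb.astype(np.float32), opt)
            ep_losses.append(loss)
        metric = _epoch_metric(net, cfg.task, Xv[..., None], yv, side,
                               batch_size=cfg.batch_size)
        hist.append({"epoch": epoch, "train_loss": float(np.mean(ep_losses)),
                     ("val_accuracy" if is_clf else "val_rmse_px"): metric})
        better = (best_metric is None
                  or (is_clf and metric > best_metric)
                  or (not is_clf and metric < best_metric))
        if better:
            best_metric, best_epoch, best_weights = metric, epoch, net.get_weights()
        if verbose:
            print(f"epoch {epoch:3d} loss {np.mean(ep_losses):.4f} val {metric:.4f}")
    net.set_weights(best_weights)
    net.release_buffers()
    return TrainedModel(network=net, config=cfg,
                        history=pd.DataFrame(hist), selected_epoch=best_epoch)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model: weights (npz) with embedded config/history."""
    import json
    weights = model.network.get_weights()
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    arrays["history_json"] = np.frombuffer(
        model.history.to_json().encode(), dtype=np.uint8)
    arrays["selected_epoch"] = np.array([model.selected_epoch])
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    """Load a model written by :func:`save_model`."""
    import json
    with np.load(path) as data:
        cfg_d = json.loads(bytes(data["config_json"]).decode())
        cfg_d["kernel"] = tuple(cfg_d["kernel"])
        cfg = ModelConfig(**cfg_d)
        hist = pd.read_json(io.StringIO(bytes(data["history_json"]).decode()))
        epoch = int(data["selected_epoch"][0])
        n = len([k for k in data.files if k.startswith("w")])
        weights = [data[f"w{i}"] for i in range(n)]
    net = build_network(cfg)
    net.set_weights(weights)
    return TrainedModel(network=net, config=cfg, history=hist, selected_epoch=epoch)


def select_epoch(metrics: Sequence[float], mode: str) -> int:
    """Checkpoint selection: argmax accuracy / argmin RMSE, earliest tie."""
    arr = np.asarray(metrics, dtype=float)
    if mode == "accuracy":
        return int(np.argmax(arr))
    if mode == "rmse":
        return int(np.argmin(arr))
    raise ValueError("mode must be 'accuracy' or 'rmse'")


def predict_class(model: TrainedModel, img: np.ndarray) -> Prediction:
    """Class probabilities for one preprocessed model-frame image."""
    side = model.config.input_side_px
    if img.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got {img.shape}")
    p = model.network.predict(img[None, :, :, None].astype(np.float32))[0]
    return Prediction(probabilities=p)


def predict_landmark(model: TrainedModel, img: np.ndarray, log: TransformLog) -> np.ndarray:
    """Landmark prediction mapped back to original-frame mm.

    The sigmoid output in [0,1]^2 is scaled by the model-frame side length
    to pixels, then inverse-mapped through the TransformLog.
    """
    if log is None:
        raise ValueError("a TransformLog is required to report mm coordinates")
    side = model.config.input_side_px
    if img.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got {img.shape}")
    u = model.network.predict(img[None, :, :, None].astype(np.float32))[0]
    pt_px = np.asarray(u, dtype=float) * side  # (x, y) in model frame
    return log.model_px_to_original_mm(pt_px)


def encode_landmark(pt_mm, log: TransformLog, side: int) -> np.ndarray:
    """Original-frame mm point -> normalised [0,1]^2 regression target."""
    pt_px = log.original_mm_to_model_px(pt_mm)
    return np.clip(np.asarray(pt_px, dtype=float) / side, 0.0, 1.0)


# ----------------------------------------------------------------------
# sklearn-style estimators
# ----------------------------------------------------------------------

class _BaseCNN(BaseEstimator):
    _task = "classification"

    def __init__(self, input_side_px=224, width_multiplier=1.0, lr=1e-5,
                 momentum=0.0, batch_size=32, epochs=160, dropout=0.5,
                 val_fraction=0.25, augment_rotation_deg=10.0,
                 augment_shift_frac=0.05, augment_zoom_frac=0.10, seed=0):
        self.input_side_px = input_side_px
        self.width_multiplier = width_multiplier
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.val_fraction = val_fraction
        self.augment_rotation_deg = augment_rotation_deg
        self.augment_shift_frac = augment_shift_frac
        self.augment_zoom_frac = augment_zoom_frac
        self.seed = seed

    def _config(self, **extra) -> ModelConfig:
        return ModelConfig(
            task=self._task, input_side_px=self.input_side_px,
            width_multiplier=self.width_multiplier, lr=self.lr,
            momentum=self.momentum, batch_size=self.batch_size,
            epochs=self.epochs, dropout=self.dropout,
            val_fraction=self.val_fraction,
            augment_rotation_deg=self.augment_rotation_deg,
            augment_shift_frac=self.augment_shift_frac,
            augment_zoom_frac=self.augment_zoom_frac, seed=self.seed, **extra,
        )

    def _fit(self, X, y, cfg):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != cfg.input_side_px or X.shape[2] != cfg.input_side_px:
            raise ValueError(
                f"X must be (n, {cfg.input_side_px}, {cfg.input_side_px})"
            )
        strat = cfg.task == "classification"
        Xt, Xv, yt, yv = split_train_val(
            X, np.asarray(y), ratio=cfg.val_fraction, seed=cfg.seed, stratify=strat
        )
        net = build_network(cfg)
        trained = train_network(net, (Xt, yt), (Xv, yv), cfg)
        self.model_ = trained
        self.config_ = cfg
        self.history_ = trained.history
        self.selected_epoch_ = trained.selected_epoch
        return self


class PositioningClassifier(_BaseCNN, ClassifierMixin):
    """Binary/multiclass positioning-feature classifier (softmax CNN)."""

    _task = "classification"

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = self._config(n_classes=len(self.classes_))
        self._fit(X, y_idx, cfg)
        self.val_accuracy_ = float(self.history_["val_accuracy"].max())
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        return self.model_.network.predict(X[..., None])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class LandmarkRegressor(_BaseCNN, RegressorMixin):
    """Landmark coordinate regressor (sigmoid CNN over normalised (x, y))."""

    _task = "regression"

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2) normalised coordinates")
        if y.min() < 0 or y.max() > 1:
            raise ValueError("normalised coordinates must lie in [0, 1]")
        cfg = self._config(n_coords=2)
        self._fit(X, y, cfg)
        self.val_rmse_px_ = float(self.history_["val_rmse_px"].min())
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        return self.model_.network.predict(X[..., None])
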