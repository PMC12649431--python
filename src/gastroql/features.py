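"""Compact CNN backbone and the 64-d feature vector it feeds to the Q-agent.

Architecture (for 64x64x3 input, same padding):

    conv 32@3x3 + ReLU -> maxpool 2x2 -> conv 64@3x3 + ReLU -> maxpool 2x2
    -> flatten -> dense 64 + ReLU (the feature vector f) -> dense K (head)

The network is trained supervised on the class labels, then the head is
detached and the backbone frozen; the non-negative 64-d embedding f is the
state representation handed to the tabular Q-learning classifier.  Training
uses AdamW with batch size 32 and, by default, element-wise binary
cross-entropy of sigmoid outputs against one-hot targets (a categorical
softmax cross-entropy switch is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .data import LabeledImage, normalize_intensity

__all__ = [
    "CNNConfig",
    "PretrainConfig",
    "TrainedCNN",
    "build_cnn",
    "pretrain_cnn",
    "extract_features",
    "head_predict",
    "save_cnn",
    "load_cnn",
    "CNNFeatureExtractor",
]


@dataclass
class CNNConfig:
    input_size: int = 64
    channels: int = 3
    conv1_filters: int = 32
    conv2_filters: int = 64
    fc_dim: int = 64
    num_classes: int = 4
    padding_mode: str = "same"

    def validate(self) -> None:
        for name in ("input_size", "channels", "conv1_filters", "conv2_filters",
                     "fc_dim", "num_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError(f"unknown padding_mode {self.padding_mode!r}")


@dataclass
class PretrainConfig:
    optimizer: str = "adamw"
    loss: str = "bce"  # "bce" (element-wise, one-hot) | "softmax"
    batch_size: int = 32
    epochs: int = 10
    lr: float = 1e-3
    seed: int = 0


class TrainedCNN:
    """Weight container for the backbone + classification head."""

    def __init__(self, config: CNNConfig, seed: int):
        config.validate()
        self.config = config
        self.frozen = False
        self.history: list[float] = []
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = nn.Conv2D(c.channels, c.conv1_filters, 3, rng, c.padding_mode)
        self.conv2 = nn.Conv2D(c.conv1_filters, c.conv2_filters, 3, rng, c.padding_mode)
        flat_dim = self._flat_dim()
        self.fc = nn.Dense(flat_dim, c.fc_dim, rng)
        self.head = nn.Dense(c.fc_dim, c.num_classes, rng)

    def _flat_dim(self) -> int:
        c = self.config
        probe = nn.Tensor(np.zeros((1, c.channels, c.input_size, c.input_size), np.float32))
        out = nn.maxpool2x2(self.conv2(nn.maxpool2x2(self.conv1(probe))))
        return int(np.prod(out.shape[1:]))

    @property
    def params(self) -> list[nn.Tensor]:
        return nn.collect_params(self.conv1, self.conv2, self.fc, self.head)

    @property
    def backbone_params(self) -> list[nn.Tensor]:
        return nn.collect_params(self.conv1, self.conv2, self.fc)

    def features_tensor(self, x: nn.Tensor) -> nn.Tensor:
        a1 = nn.maxpool2x2(nn.relu(self.conv1(x)))
        a2 = nn.maxpool2x2(nn.relu(self.conv2(a1)))
        flat = nn.reshape(a2, (a2.shape[0], -1))
        return nn.relu(self.fc(flat))

    def logits_tensor(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.features_tensor(x))


def build_cnn(config: CNNConfig, seed: int) -> TrainedCNN:
    """Seeded, untrained network with the configured architecture."""
    return TrainedCNN(config, seed)


def _to_nchw(images, input_size: int, channels: int) -> np.ndarray:
    """Accept LabeledImage lists or (N,H,W,C)/(H,W,C) arrays in [0, 1]."""
    if isinstance(images, LabeledImage):
        images = [images]
    if isinstance(images, (list, tuple)):
        arr = np.stack([normalize_intensity(r.pixels) if isinstance(r, LabeledImage)
                        else np.asarray(r, np.float32) for r in images])
    else:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
    if arr.ndim != 4 or arr.shape[1:] != (input_size, input_size, channels):
        raise ValueError(
            f"expected images of shape (n, {input_size}, {input_size}, {channels}), "
            f"got {arr.shape}")
    if arr.max(initial=0.0) > 1.0 + 1e-6 or arr.min(initial=0.0) < 0.0:
        raise ValueError("images must be normalized to [0, 1]")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2), dtype=np.float32)


def pretrain_cnn(model: TrainedCNN, train, cfg: PretrainConfig,
                 labels=None) -> TrainedCNN:
    """Supervised training of the full network, then freeze the backbone.

    ``train`` is a list of LabeledImage or an (n, H, W, C) array in [0, 1]
    (with ``labels`` given separately in the latter case).  With
    ``epochs=0`` the weights stay at their seeded initialisation.
    """
    if labels is None:
        if not train:
            raise ValueError("empty training set")
        labels = np.array([r.label for r in train], dtype=np.int64)
    else:
        labels = np.asarray(labels, dtype=np.int64)
    x = _to_nchw(train, model.config.input_size, model.config.channels)
    if len(x) == 0:
        raise ValueError("empty training set")
    k = model.config.num_classes
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label outside [0, num_classes)")
    if model.frozen:
        raise RuntimeError("model is frozen; build a fresh one to retrain")
    if cfg.optimizer.lower() == "adamw":
        opt = nn.AdamW(model.params, lr=cfg.lr)
    elif cfg.optimizer.lower() == "adam":
        opt = nn.Adam(model.params, lr=cfg.lr)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    onehot = np.eye(k, dtype=np.float32)[labels]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.logits_tensor(nn.Tensor(x[idx]))
            if cfg.loss == "bce":
                loss = nn.bce(nn.sigmoid(logits), onehot[idx])
            elif cfg.loss == "softmax":
                loss = nn.softmax_ce(logits, labels[idx])
            else:
                raise ValueError(f"unknown loss {cfg.loss!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.history.append(float(np.mean(losses)))
    model.frozen = True
    return model


def extract_features(model: TrainedCNN, image) -> np.ndarray:
    """64-d non-negative embedding of one image (or a batch).

    Requires a frozen model so the mapping is stationary; returns (64,)
    for a single image and (n, 64) for a batch.
    """
    if not model.frozen:
        raise RuntimeError("extract_features requires a frozen (pretrained) model")
    single = isinstance(image, LabeledImage) or (
        isinstance(image, np.ndarray) and image.ndim == 3)
    x = _to_nchw(image, model.config.input_size, model.config.channels)
    feats = model.features_tensor(nn.Tensor(x)).data
    return feats[0] if single else feats


def head_predict(model: TrainedCNN, images) -> np.ndarray:
    """Class predictions of the supervised head (argmax of the logits)."""
    x = _to_nchw(images, model.config.input_size, model.config.channels)
    return model.logits_tensor(nn.Tensor(x)).data.argmax(axis=1)


def save_cnn(model: TrainedCNN, path) -> None:
    """Single-file .npz checkpoint (weights + config + frozen flag)."""
    import json

    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    arrays["config_json"] = np.frombuffer(
        json.dumps({**model.config.__dict__, "frozen": model.frozen}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_cnn(path) -> TrainedCNN:
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["config_json"].tobytes()).decode())
        frozen = meta.pop("frozen")
        model = TrainedCNN(CNNConfig(**meta), seed=0)
        for i, p in enumerate(model.params):
            p.data = npz[f"p{i}"].astype(np.float32)
    model.frozen = frozen
    return model


class CNNFeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn transformer: supervised CNN pretraining, frozen feature maps.

    ``fit(X, y)`` trains the network (including the classification head) on
    images ``X`` of shape (n, size, size, 3) scaled to [0, 1]; ``transform``
    returns the frozen 64-d embeddings used as Q-learning states.

    Parameters mirror the backbone architecture and the supervised
    training protocol (AdamW, batch size 32 by default).
    """

    def __init__(self, input_size: int = 64, conv1_filters: int = 32,
                 conv2_filters: int = 64, fc_dim: int = 64,
                 padding_mode: str = "same", loss: str = "bce",
                 optimizer: str = "adamw", epochs: int = 10,
                 batch_size: int = 32, lr: float = 1e-3, random_state: int = 0):
        self.input_size = input_size
        self.conv1_filters = conv1_filters
        self.conv2_filters = conv2_filters
        self.fc_dim = fc_dim
        self.padding_mode = padding_mode
        self.loss = loss
        self.optimizer = optimizer
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        config = CNNConfig(input_size=self.input_size,
                           conv1_filters=self.conv1_filters,
                           conv2_filters=self.conv2_filters,
                           fc_dim=self.fc_dim,
                           num_classes=int(self.classes_.size),
                           padding_mode=self.padding_mode)
        cfg = PretrainConfig(optimizer=self.optimizer, loss=self.loss,
                             batch_size=self.batch_size, epochs=self.epochs,
                             lr=self.lr, seed=self.random_state)
        model = build_cnn(config, seed=self.random_state)
        labels = np.searchsorted(self.classes_, y)
        self.cnn_ = pretrain_cnn(model, np.asarray(X, np.float32), cfg, labels=labels)
        self.n_features_out_ = config.fc_dim
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "cnn_")
        return extract_features(self.cnn_, np.asarray(X, np.float32))
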