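"""Attention-gated U-Net for binary lesion segmentation.

Encoder blocks are two 3x3 convolutions with ReLU followed by 2x2 max
pooling; the decoder upsamples with 2x2 stride-2 transposed convolutions.
Before each skip concatenation an additive attention gate rescales the
encoder features: both the skip tensor x and the coarser gating signal g
are projected with 1x1 convolutions, g is bilinearly resized to x's
spatial dims, and the per-location attention coefficient is

    alpha = sigmoid( psi( ReLU( Wf*x + Wg*g ) ) ),   x' = alpha * x

with psi a 1x1 single-channel projection.  Since sigmoid is strictly
inside (0, 1), so is every coefficient; with all gate parameters zero the
gate is exactly a 0.5 scaling of x.  The head is a 1x1 convolution with a
sigmoid, trained with pixel-wise binary cross-entropy under Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nn
from .metrics import dice_score, pixel_accuracy

__all__ = [
    "UNetConfig",
    "SegTrainConfig",
    "AttentionGate",
    "attention_gate",
    "AttentionUNet",
    "build_attention_unet",
    "train_segmenter",
    "predict_mask",
    "save_unet",
    "load_unet",
    "AttentionUNetSegmenter",
]


@dataclass
class UNetConfig:
    input_size: int = 128
    in_channels: int = 3
    depth: int = 4
    base_filters: int = 16
    attention_on_skips: bool = True

    def validate(self) -> None:
        if self.depth < 1 or self.base_filters < 1 or self.in_channels < 1:
            raise ValueError("depth, base_filters and in_channels must be positive")
        if self.input_size % (2 ** self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2 ** self.depth}")


@dataclass
class SegTrainConfig:
    batch_size: int = 8
    epochs: int = 50
    lr: float = 1e-3
    seed: int = 0
    threshold: float = 0.5
    early_stop_dice: float | None = None  # stop once validation Dice reaches this


class AttentionGate(nn.Layer):
    """Additive attention gate over one skip connection."""

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator):
        super().__init__()
        inter = max(skip_ch // 2, 1)
        self.wf = nn.Conv2D(skip_ch, inter, 1, rng)
        self.wg = nn.Conv2D(gate_ch, inter, 1, rng)
        self.psi = nn.Conv2D(inter, 1, 1, rng)
        self.params = nn.collect_params(self.wf, self.wg, self.psi)

    def __call__(self, x: nn.Tensor, g: nn.Tensor) -> nn.Tensor:
        f = self.wf(x)
        g1 = self.wg(g)
        if g1.shape[2:] != f.shape[2:]:
            g1 = nn.resize_bilinear(g1, f.shape[2], f.shape[3])
        alpha = nn.sigmoid(self.psi(nn.relu(nn.add(f, g1))))
        return nn.mul(alpha, x)

    def coefficients(self, x: nn.Tensor, g: nn.Tensor) -> np.ndarray:
        """The per-location attention map alpha (values strictly in (0,1))."""
        f = self.wf(x)
        g1 = self.wg(g)
        if g1.shape[2:] != f.shape[2:]:
            g1 = nn.resize_bilinear(g1, f.shape[2], f.shape[3])
        return nn.sigmoid(self.psi(nn.relu(nn.add(f, g1)))).data


def attention_gate(x, g, params: AttentionGate):
    """Functional form of the gate: gated skip features alpha * x."""
    xt = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, np.float32))
    gt = g if isinstance(g, nn.Tensor) else nn.Tensor(np.asarray(g, np.float32))
    return params(xt, gt)


class _ConvBlock(nn.Layer):
    """Two 3x3 same-padding convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = nn.Conv2D(in_ch, out_ch, 3, rng)
        self.c2 = nn.Conv2D(out_ch, out_ch, 3, rng)
        self.params = nn.collect_params(self.c1, self.c2)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class AttentionUNet:
    """The segmentation network; emits per-pixel foreground probabilities."""

    def __init__(self, config: UNetConfig, seed: int):
        config.validate()
        self.config = config
        self.history: dict[str, list[float]] = {
            "train_loss": [], "val_loss": [], "val_dice": [], "val_accuracy": []}
        rng = np.random.default_rng(seed)
        c = config
        chans = [c.base_filters * 2 ** i for i in range(c.depth + 1)]
        self.encoder = []
        in_ch = c.in_channels
        for ch in chans[:-1]:
            self.encoder.append(_ConvBlock(in_ch, ch, rng))
            in_ch = ch
        self.bridge = _ConvBlock(chans[-2], chans[-1], rng)
        self.ups, self.gates, self.decoder = [], [], []
        for level in reversed(range(c.depth)):
            coarse, fine = chans[level + 1], chans[level]
            self.ups.append(nn.ConvTranspose2D(coarse, fine, rng))
            self.gates.append(AttentionGate(fine, coarse, rng) if c.attention_on_skips else None)
            self.decoder.append(_ConvBlock(2 * fine, fine, rng))
        self.final = nn.Conv2D(chans[0], 1, 1, rng)

    @property
    def params(self) -> list[nn.Tensor]:
        layers = [*self.encoder, self.bridge, *self.ups,
                  *(g for g in self.gates if g is not None), *self.decoder, self.final]
        return nn.collect_params(*layers)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.config.in_channels or \
                x.shape[2] % (2 ** self.config.depth) or x.shape[3] % (2 ** self.config.depth):
            raise ValueError(f"bad input shape {x.shape} for depth {self.config.depth}")
        skips = []
        h = x
        for block in self.encoder:
            h = block(h)
            skips.append(h)
            h = nn.maxpool2x2(h)
        h = self.bridge(h)
        for up, gate, block, skip in zip(self.ups, self.gates, self.decoder, reversed(skips)):
            gated = gate(skip, h) if gate is not None else skip
            h = block(nn.concat_channels([up(h), gated]))
        return nn.sigmoid(self.final(h))


def build_attention_unet(config: UNetConfig, seed: int) -> AttentionUNet:
    """Seeded attention U-Net (plain U-Net if attention is disabled)."""
    return AttentionUNet(config, seed)


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple):
        x, y = (np.asarray(a, np.float32) for a in pairs)
    else:
        if not pairs:
            raise ValueError("empty segmentation pair list")
        x = np.stack([p.image for p in pairs]).astype(np.float32)
        y = np.stack([p.mask for p in pairs]).astype(np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)), y[:, None, :, :]


def train_segmenter(model: AttentionUNet, pairs_train, cfg: SegTrainConfig,
                    pairs_val=None) -> AttentionUNet:
    """Minimise pixel-wise BCE with Adam; record per-epoch curves.

    ``pairs_train``/``pairs_val`` are lists of SegPair or (images, masks)
    array tuples; images in [0, 1], masks binary.  Validation Dice and
    pixel accuracy are computed on thresholded predictions each epoch.
    """
    x, y = _pairs_to_arrays(pairs_train)
    if len(x) == 0:
        raise ValueError("empty training set")
    opt = nn.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            prob = model.forward(nn.Tensor(x[idx]))
            loss = nn.bce(prob, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.history["train_loss"].append(float(np.mean(losses)))
        if pairs_val is not None:
            vx, vy = _pairs_to_arrays(pairs_val)
            vloss, dices, accs = [], [], []
            for start in range(0, len(vx), cfg.batch_size):
                sl = slice(start, start + cfg.batch_size)
                prob = model.forward(nn.Tensor(vx[sl]))
                vloss.append(float(nn.bce(prob, vy[sl]).data) * len(prob.data))
                pred = (prob.data >= cfg.threshold).astype(np.uint8)
                truth = vy[sl].astype(np.uint8)
                for j in range(len(pred)):
                    dices.append(dice_score(truth[j, 0], pred[j, 0]))
                    accs.append(pixel_accuracy(truth[j, 0], pred[j, 0]))
            model.history["val_loss"].append(float(np.sum(vloss) / len(vx)))
            model.history["val_dice"].append(float(np.mean(dices)))
            model.history["val_accuracy"].append(float(np.mean(accs)))
            if cfg.early_stop_dice is not None and \
                    model.history["val_dice"][-1] >= cfg.early_stop_dice:
                break
    return model


def predict_mask(model: AttentionUNet, image,
                 threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(probability map, binary mask) for one (H, W, C) image in [0, 1]."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError(f"expected one (H, W, C) image, got shape {arr.shape}")
    x = np.ascontiguousarray(arr.transpose(2, 0, 1))[None]
    prob = model.forward(nn.Tensor(x)).data[0, 0]
    return prob, (prob >= threshold).astype(np.uint8)


def save_unet(model: AttentionUNet, path) -> None:
    """Single-file .npz checkpoint (weights + architecture config)."""
    import json

    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_unet(path) -> AttentionUNet:
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["config_json"].tobytes()).decode())
        model = AttentionUNet(UNetConfig(**meta), seed=0)
        for i, p in enumerate(model.params):
            p.data = npz[f"p{i}"].astype(np.float32)
    return model


class AttentionUNetSegmenter(BaseEstimator):
    """Sklearn-style estimator around the attention U-Net.

    ``fit(X, y)`` takes images (n, H, W, C) in [0, 1] and binary masks
    (n, H, W); optional ``X_val``/``y_val`` drive the per-epoch validation
    curves and early stopping.  ``predict`` returns binary masks,
    ``predict_proba`` the probability maps, and ``score`` the mean Dice.
    """

    def __init__(self, input_size: int = 128, in_channels: int = 3,
                 depth: int = 4, base_filters: int = 16,
                 attention_on_skips: bool = True, epochs: int = 50,
                 batch_size: int = 8, lr: float = 1e-3,
                 threshold: float = 0.5, early_stop_dice: float | None = None,
                 random_state: int = 0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.depth = depth
        self.base_filters = base_filters
        self.attention_on_skips = attention_on_skips
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.threshold = threshold
        self.early_stop_dice = early_stop_dice
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        config = UNetConfig(input_size=self.input_size, in_channels=self.in_channels,
                            depth=self.depth, base_filters=self.base_filters,
                            attention_on_skips=self.attention_on_skips)
        cfg = SegTrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                             lr=self.lr, seed=self.random_state,
                             threshold=self.threshold,
                             early_stop_dice=self.early_stop_dice)
        model = build_attention_unet(config, seed=self.random_state)
        val = (np.asarray(X_val, np.float32), np.asarray(y_val, np.float32)) \
            if X_val is not None else None
        self.unet_ = train_segmenter(
            model, (np.asarray(X, np.float32), np.asarray(y, np.float32)), cfg, val)
        self.history_ = model.history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "unet_")
        x, _ = _pairs_to_arrays((np.asarray(X, np.float32),
                                 np.zeros((len(X), 1, 1), np.float32)))
        out = []
        for start in range(0, len(x), self.batch_size):
            out.append(self.unet_.forward(nn.Tensor(x[start : start + self.batch_size])).data[:, 0])
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given pairs."""
        preds = self.predict(X)
        y = np.asarray(y).astype(np.uint8)
        return float(np.mean([dice_score(y[i], preds[i]) for i in range(len(y))]))
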