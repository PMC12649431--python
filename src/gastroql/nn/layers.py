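"""Parameterised layers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Layer:
    """Base class: subclasses register parameters in ``self.params``."""

    def __init__(self):
        self.params: list[Tensor] = []

    def _param(self, data: np.ndarray) -> Tensor:
        t = Tensor(data.astype(np.float32), requires_grad=True)
        self.params.append(t)
        return t


class Conv2D(Layer):
    """3x3 (or 1x1) convolution, stride 1, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: str = "same"):
        super().__init__()
        if in_ch <= 0 or out_ch <= 0 or kernel <= 0:
            raise ValueError("layer dimensions must be positive")
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = self._param(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)))
        self.b = self._param(np.zeros(out_ch))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.w, self.b, self.padding)


class ConvTranspose2D(Layer):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("layer dimensions must be positive")
        scale = np.sqrt(2.0 / (in_ch * 4))
        self.w = self._param(rng.normal(0.0, scale, (in_ch, out_ch, 2, 2)))
        self.b = self._param(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv_transpose2x2(x, self.w, self.b)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        if in_dim <= 0 or out_dim <= 0:
            raise ValueError("layer dimensions must be positive")
        scale = np.sqrt(2.0 / in_dim)
        self.w = self._param(rng.normal(0.0, scale, (in_dim, out_dim)))
        self.b = self._param(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.w), self.b)


def collect_params(*layers: Layer) -> list[Tensor]:
    out: list[Tensor] = []
    for layer in layers:
        out.extend(layer.params)
    return out
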