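"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the package's two networks need:
dense and 2-D convolutional layers, 2x2 max pooling, stride-2 transposed
convolution, bilinear resizing, ReLU/sigmoid nonlinearities, channel
concatenation and broadcasting add/multiply.  Arrays use the NCHW layout.
Gradients of every op are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "reshape",
    "conv2d",
    "maxpool2x2",
    "conv_transpose2x2",
    "resize_bilinear",
    "concat_channels",
    "mean",
    "bce",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep U-Net graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return _make(np.where(mask, x.data, 0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # piecewise form avoids overflow in exp for large |x|
    pos = x.data >= 0
    ex = np.exp(np.where(pos, -x.data, x.data))
    s = np.where(pos, 1.0 / (1.0 + ex), ex / (1.0 + ex))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, float(g) / n))

    return _make(np.asarray(x.data.mean()), (x,), backward)


# ---------------------------------------------------------------------------
# convolution and friends (NCHW layout)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Patches of a padded NCHW array -> (N*OH*OW, C*kh*kw) matrix."""
    n, c, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # view: (N, C, OH, OW, kh, kw) -> (N, OH, OW, C, kh, kw)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: str = "same") -> Tensor:
    """2-D convolution, stride 1, 'same' or 'valid' padding.

    x: (N, C, H, W);  w: (F, C, kh, kw);  b: (F,).
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, filters expect {c2}")
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    oh, ow = h + 2 * ph - kh + 1, wd + 2 * pw - kw + 1
    cols = _im2col(xp, kh, kw)
    wmat = w.data.reshape(f, -1)
    out = (cols @ wmat.T + b.data).reshape(n, oh, ow, f).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
        w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        b._accumulate(gmat.sum(axis=0))
        gcols = (gmat @ wmat).reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + oh, j : j + ow] += gcols[:, :, :, :, i, j]
        if ph or pw:
            gxp = gxp[:, :, ph : ph + h, pw : pw + wd]
        x._accumulate(gxp)

    return _make(out, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    n, c, h, w = x.data.shape
    oh, ow = h // 2, w // 2
    if oh == 0 or ow == 0:
        raise ValueError("input too small for 2x2 pooling")
    cropped = x.data[:, :, : 2 * oh, : 2 * ow]
    windows = cropped.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : 2 * oh, : 2 * ow] = (
            gw.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * oh, 2 * ow)
        )
        x._accumulate(gx)

    return _make(out, (x,), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution, kernel 2x2 stride 2 (exact 2x upsampling).

    x: (N, C, H, W);  w: (C, F, 2, 2);  b: (F,).  Output (N, F, 2H, 2W).
    """
    n, c, h, wd = x.data.shape
    c2, f, _, _ = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, filters expect {c2}")
    out6 = np.einsum("nchw,cfij->nfhwij", x.data, w.data, optimize=True)
    out = out6.transpose(0, 1, 2, 4, 3, 5).reshape(n, f, 2 * h, 2 * wd)
    out = out + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(n, f, h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.einsum("nfhwij,cfij->nchw", g6, w.data, optimize=True))
        w._accumulate(np.einsum("nchw,nfhwij->cfij", x.data, g6, optimize=True))
        b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, (x, w, b), backward)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor; separable, hence two matmuls."""
    n, c, h, w = x.data.shape
    lh = _bilinear_matrix(out_h, h, x.data.dtype)
    lw = _bilinear_matrix(out_w, w, x.data.dtype)
    out = np.einsum("oh,nchw,pw->ncop", lh, x.data, lw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,ncop,pw->nchw", lh, g, lw, optimize=True))

    return _make(out, (x,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._accumulate(g[:, lo:hi])

    return _make(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors), backward)


def softmax_ce(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) vs integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-30)).mean()

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(float(g) * grad / n)

    return _make(np.asarray(loss), (logits,), backward)


def bce(pred: Tensor, target: np.ndarray, clip: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy -mean[y log p + (1-y) log(1-p)].

    Predictions are clipped to [clip, 1-clip] before the logarithm.
    """
    y = np.asarray(target, dtype=pred.data.dtype)
    p = np.clip(pred.data, clip, 1.0 - clip)
    loss = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean()

    def backward(g):
        inside = (pred.data > clip) & (pred.data < 1.0 - clip)
        grad = np.where(inside, (p - y) / (p * (1.0 - p)), 0.0) / y.size
        pred._accumulate(float(g) * grad)

    return _make(np.asarray(loss), (pred,), backward)
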