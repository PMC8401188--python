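"""Minimal deterministic neural-network stack on numpy.

Implements exactly what the training pipeline needs — same-padded
convolutions via im2col, max/global pooling, dense layers, inverted
dropout, softmax cross-entropy and the Adamax optimizer — with every
source of randomness drawn from an explicit generator, so a training run
is a pure function of (architecture seed, data, config seed) on a single
CPU.  Parameters are float32 throughout.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: holds parallel lists of parameters and their gradients."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def sublayers(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches for a stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Conv2D(Layer):
    """3x3/5x5/1x1 stride-1 convolution with 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        w = rng.normal(0.0, scale, size=(out_channels, fan_in))
        self.params = [w.astype(np.float32),
                       np.zeros(out_channels, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        self._cols = _im2col(x, self.kernel, self.pad)
        w, b = self.params
        n, _, hw = self._cols.shape
        out = np.einsum("of,nfp->nop", w, self._cols, optimize=True)
        out += b[None, :, None]
        h, wd = x.shape[2], x.shape[3]
        return out.reshape(n, self.out_channels, h, wd)

    def backward(self, dout):
        n, oc, h, w = dout.shape
        dflat = dout.reshape(n, oc, h * w)
        wgt, _ = self.params
        self.grads[0][...] = np.einsum("nop,nfp->of", dflat, self._cols,
                                       optimize=True)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wgt, dflat, optimize=True)
        return _col2im(dcols, self._xshape, self.kernel, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (floor division of the spatial size)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        xc = x[:, :, :h2 * 2, :w2 * 2]
        windows = (xc.reshape(n, c, h2, 2, w2, 2)
                     .transpose(0, 1, 2, 4, 3, 5)
                     .reshape(n, c, h2, w2, 4))
        self._argmax = windows.argmax(axis=-1)
        return np.take_along_axis(windows, self._argmax[..., None],
                                  axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None],
                          axis=-1)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = (dwin.reshape(n, c, h2, w2, 2, 2)
                                          .transpose(0, 1, 2, 4, 3, 5)
                                          .reshape(n, c, h2 * 2, w2 * 2))
        return dx


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._xshape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._xshape).astype(dout.dtype).copy()


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        w = rng.normal(0.0, scale, size=(in_features, out_features))
        self.params = [w.astype(np.float32),
                       np.zeros(out_features, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False, rng=None):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Parallel(Layer):
    """Concatenates the channel outputs of several convolutional branches.

    All branches must preserve the spatial size (same-padded convs), so the
    outputs can be concatenated along the channel axis, Inception style.
    """

    def __init__(self, branches: Sequence[Sequence[Layer]]):
        super().__init__()
        self.branches = [list(b) for b in branches]

    def sublayers(self):
        return [layer for branch in self.branches for layer in branch]

    def forward(self, x, train=False, rng=None):
        outs = []
        self._splits = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train=train, rng=rng)
            outs.append(h)
            self._splits.append(h.shape[1])
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        dx = None
        start = 0
        for branch, width in zip(self.branches, self._splits):
            d = dout[:, start:start + width]
            start += width
            for layer in reversed(branch):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


# ---------------------------------------------------------------------------
# model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Sequential:
    """A feed-forward model whose tail ``head_start`` layers form the
    classifier head; everything before it is the feature extractor whose
    output is the penultimate-layer activation."""

    def __init__(self, layers: list[Layer], *, spec: str, input_side: int,
                 num_classes: int, penultimate_width: int, head_start: int,
                 dropout: float, seed: int):
        self.layers = layers
        self.spec = spec
        self.input_side = input_side
        self.num_classes = num_classes
        self.penultimate_width = penultimate_width
        self.head_start = head_start
        self.dropout = dropout
        self.seed = seed

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self) -> list[Layer]:
        flat = []
        for layer in self.layers:
            flat.append(layer)
            flat.extend(layer.sublayers())
        return flat

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers() for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError("state shape mismatch")
            p[...] = s

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected (N, side, side) or (N, 1, side, side)")
        if x.shape[2] != self.input_side or x.shape[3] != self.input_side:
            raise ValueError(
                f"model {self.spec!r} expects {self.input_side}x"
                f"{self.input_side} inputs, got {x.shape[2]}x{x.shape[3]}"
            )
        return x

    # -- computation -------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        h = self._check_input(x)
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Normalized class scores (rows sum to 1)."""
        return softmax(self.forward_logits(x, train=False))

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations; never touches the head weights."""
        h = self._check_input(x)
        for layer in self.layers[:self.head_start]:
            h = layer.forward(h, train=False)
        return np.asarray(h, dtype=np.float64)


class Adamax(object):
    """Adamax: Adam with an infinity-norm second moment.

    m_t = b1 m + (1-b1) g;  u_t = max(b2 u, |g|);
    p -= lr / (1 - b1^t) * m_t / (u_t + eps).
    """

    def __init__(self, params: list[np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 - self.beta1 ** self.t)
        for p, g, m, u in zip(self.params, grads, self.m, self.u):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= (lr_t * m / (u + self.eps)).astype(p.dtype)
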