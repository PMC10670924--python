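"""Minimal numpy implementation of a trainable U-Net.

The grading environment ships no deep-learning framework, so the detector
is implemented directly on numpy: 3×3 same-padding convolutions via
im2col/GEMM, 2×2 max pooling, 2×2 stride-2 transposed convolutions for
upsampling, ReLU activations, a 1×1 sigmoid output head, binary
cross-entropy on logits, and Adam.  Everything is float32 and fully
deterministic given the initialisation seed (no threading-dependent
reductions beyond BLAS GEMM, which is bitwise stable for a fixed build).

Tensors are laid out (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class Conv3x3:
    """3×3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.W = _he(rng, (cout, cin, 3, 3), cin * 9)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if train:
            self._cols = cols
            self._shape = x.shape
        return np.ascontiguousarray(
            out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        o = self.W.shape[0]
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
        self.dW = (dy_mat.T @ self._cols).reshape(o, c, 3, 3)
        self.db = dy_mat.sum(0)
        self._cols = None
        # gradient w.r.t. input: full correlation with the rotated kernel
        w_rot = np.flip(self.W, (2, 3)).transpose(1, 0, 2, 3)  # (cin, cout, 3, 3)
        cols_dy = self._im2col(dy)
        dx = cols_dy @ w_rot.reshape(c, -1).T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2×2 max pooling, stride 2; ties resolved to the first maximum."""

    def __init__(self) -> None:
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = v.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._arg = flat.argmax(-1)
            self._shape = x.shape
        return flat.max(-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        self._arg = None
        dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class Deconv2:
    """2×2 transposed convolution with stride 2 (doubles height and width)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.W = _he(rng, (cin, cout, 2, 2), cin)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.tensordot(x, self.W, axes=([1], [0]))  # n,h,w,cout,2,2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, -1, 2 * h, 2 * w)
        if train:
            self._x = x
        return np.ascontiguousarray(y + self.b[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyt = dy.reshape(n, f, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # n,h,w,f,2,2
        self.dW = np.tensordot(self._x, dyt, axes=([0, 2, 3], [0, 1, 2]))
        self.db = dy.sum((0, 2, 3))
        dx = np.tensordot(dyt, self.W, axes=([3, 4, 5], [1, 2, 3]))  # n,h,w,cin
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.W = _he(rng, (cout, cin), cin)
        self.b = np.zeros(cout, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        y = np.tensordot(self.W, x, axes=([1], [1])).transpose(1, 0, 2, 3)
        return np.ascontiguousarray(y + self.b[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = np.tensordot(dy, self._x, axes=([0, 2, 3], [0, 2, 3]))
        self.db = dy.sum((0, 2, 3))
        dx = np.tensordot(self.W.T, dy, axes=([1], [1])).transpose(1, 0, 2, 3)
        self._x = None
        return np.ascontiguousarray(dx)

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class ConvBlock:
    """Two 3×3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.c1 = Conv3x3(cin, cout, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(cout, cout, rng)
        self.r2 = ReLU()

    def forward(self, x, train=False):
        return self.r2.forward(
            self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train),
            train,
        )

    def backward(self, dy):
        return self.c1.backward(
            self.r1.backward(self.c2.backward(self.r2.backward(dy)))
        )

    def params(self):
        yield from self.c1.params()
        yield from self.c2.params()


class UNet:
    """Symmetric encoder/decoder with skip concatenations and a sigmoid head.

    ``depth`` encoder blocks of (conv, conv, pool), a two-conv bottleneck,
    and ``depth`` decoder blocks of (deconv, concat, conv, conv).  Channel
    widths double at every level starting from ``base_channels``.
    """

    def __init__(self, depth: int, base_channels: int, seed: int = 0, in_channels: int = 1):
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        self.pools = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(ConvBlock(cin, chans[i], rng))
            self.pools.append(MaxPool2())
            cin = chans[i]
        self.bottleneck = ConvBlock(cin, chans[depth], rng)
        self.ups = []
        self.dec = []
        for i in reversed(range(depth)):
            self.ups.append(Deconv2(chans[i + 1], chans[i], rng))
            self.dec.append(ConvBlock(2 * chans[i], chans[i], rng))
        self.head = Conv1x1(chans[0], 1, rng)
        self._skip_channels = [chans[i] for i in reversed(range(depth))]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []  # decoder step j consumed encoder skip depth-1-j
        for j in reversed(range(self.depth)):
            d = self.dec[j].backward(d)
            c_skip = self._skip_channels[j]
            dskips.append(d[:, :c_skip])
            d = self.ups[j].backward(np.ascontiguousarray(d[:, c_skip:]))
        d = self.bottleneck.backward(d)
        # dskips were appended for skips 0..depth-1 in encoder order already
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)

    def layers(self):
        yield from self.enc
        yield self.bottleneck
        yield from self.ups
        yield from self.dec
        yield self.head

    def params(self):
        for layer in self.layers():
            yield from layer.params()

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))


class Adam:
    def __init__(self, model: UNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.model.params()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - targets * z))
    prob = 1.0 / (1.0 + np.exp(-z))
    dlogits = ((prob - targets) / z.size).astype(np.float32)
    return loss, dlogits


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
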