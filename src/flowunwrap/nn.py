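"""Minimal CPU neural-network engine for volumetric segmentation.

A compact, dependency-free layer library sufficient for the dense-block U-Net
in :mod:`flowunwrap.cnn`: 3D convolution (stride 1, "same" padding, arbitrary
odd kernels), ReLU, inverted dropout, in-plane 2x2 max pooling and nearest
upsampling, channel concatenation, and Adam.  Convolutions are evaluated as a
sum of shifted GEMMs (one matrix product per kernel tap), which keeps all the
arithmetic inside BLAS; gradients are computed analytically by each layer.

Tensors are ``float32`` arrays of shape ``(X, Y, Z, C)`` (one volume at a
time — the toolkit trains with batch accumulation rather than batched
tensors).  Every layer exposes ``forward(x, train)`` / ``backward(dy)`` and
caches what it needs in between; parameters are ``Param`` objects the
optimizer updates in place.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "ReLU",
    "Dropout",
    "MaxPool2x2",
    "Upsample2x2",
    "DenseBlock",
    "Adam",
    "softmax",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.ascontiguousarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """Stride-1 "same" 3D convolution with odd kernel dims (e.g. 3x3x3 or 1x1x1).

    He-normal initialization from the supplied generator; ``zero_init`` gives
    zero weights and an explicit bias (used for the background-biased head).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        bias_init: np.ndarray | None = None,
        zero_init: bool = False,
    ) -> None:
        if any(k % 2 == 0 or k < 1 for k in kernel):
            raise ValueError(f"kernel dims must be odd and positive, got {kernel}")
        self.c_in, self.c_out, self.kernel = c_in, c_out, tuple(kernel)
        fan_in = c_in * int(np.prod(kernel))
        if zero_init:
            w = np.zeros(kernel + (c_in, c_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=kernel + (c_in, c_out))
        b = np.zeros(c_out) if bias_init is None else np.asarray(bias_init, dtype=np.float32)
        self.w, self.b = Param(w), Param(b)
        self._col: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad(self):
        return tuple(k // 2 for k in self.kernel)

    @staticmethod
    def _im2col(xp: np.ndarray, out_shape, kernel) -> np.ndarray:
        """Columns (n_voxels, prod(kernel)*C) gathering each voxel's receptive field."""
        X, Y, Z = out_shape
        n = X * Y * Z
        cols = [
            xp[a : a + X, b : b + Y, c : c + Z, :].reshape(n, -1)
            for a in range(kernel[0])
            for b in range(kernel[1])
            for c in range(kernel[2])
        ]
        return cols[0] if len(cols) == 1 else np.concatenate(cols, axis=1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        px, py, pz = self._pad()
        X, Y, Z, _ = x.shape
        if px or py or pz:
            xp = np.pad(x, ((px, px), (py, py), (pz, pz), (0, 0)))
        else:
            xp = x
        col = self._im2col(xp, (X, Y, Z), self.kernel)
        if train:
            self._col = col
            self._shape = x.shape
        wmat = self.w.value.reshape(-1, self.c_out)
        out = col @ wmat + self.b.value
        return out.reshape(X, Y, Z, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._col is not None, "forward(train=True) must precede backward"
        X, Y, Z, _ = self._shape
        n = X * Y * Z
        dy = dy.astype(np.float32, copy=False)
        dyf = dy.reshape(n, self.c_out)
        self.b.grad += dyf.sum(axis=0)
        self.w.grad += (self._col.T @ dyf).reshape(self.w.grad.shape)
        self._col = None
        # gradient wrt input = full correlation of dy with the flipped kernel
        px, py, pz = self._pad()
        if px or py or pz:
            dyp = np.pad(dy, ((px, px), (py, py), (pz, pz), (0, 0)))
            dcol = self._im2col(dyp, (X, Y, Z), self.kernel)
        else:
            dcol = dyf
        # weight for tap (a,b,c) acting on dy corresponds to flipped tap order
        wflip = self.w.value[::-1, ::-1, ::-1].reshape(-1, self.c_in * self.c_out)
        wflip = wflip.reshape(-1, self.c_in, self.c_out).transpose(0, 2, 1).reshape(-1, self.c_in)
        dx = dcol @ wflip
        return dx.reshape(X, Y, Z, self.c_in)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference and when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling over (X, Y) only; Z passes through (slab counts vary)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        X, Y, Z, C = x.shape
        if X % 2 or Y % 2:
            raise ValueError(f"in-plane dims must be even to pool, got {(X, Y)}")
        # window axis of length 4: (X/2, Y/2, 4, Z, C)
        v = x.reshape(X // 2, 2, Y // 2, 2, Z, C).transpose(0, 2, 1, 3, 4, 5)
        v = np.ascontiguousarray(v).reshape(X // 2, Y // 2, 4, Z, C)
        if train:
            self._argmax = v.argmax(axis=2)  # ties -> first max, one route only
            self._shape = x.shape
        return v.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        X, Y, Z, C = self._shape
        g = np.zeros((X // 2, Y // 2, 4, Z, C), dtype=dy.dtype)
        np.put_along_axis(g, self._argmax[:, :, None, :, :], dy[:, :, None, :, :], axis=2)
        g = g.reshape(X // 2, Y // 2, 2, 2, Z, C).transpose(0, 2, 1, 3, 4, 5)
        return g.reshape(X, Y, Z, C)


class Upsample2x2(Layer):
    """Nearest-neighbor 2x upsampling over (X, Y)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=0).repeat(2, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        X2, Y2, Z, C = dy.shape
        return dy.reshape(X2 // 2, 2, Y2 // 2, 2, Z, C).sum(axis=(1, 3))


class DenseBlock(Layer):
    """A dense block: each small convolution's output (after ReLU and dropout)
    is concatenated to everything before it, so the block emits
    ``c_in + n_layers * growth`` channels."""

    def __init__(
        self,
        c_in: int,
        n_layers: int,
        growth: int,
        kernel: tuple[int, int, int],
        dropout: float,
        rng: np.random.Generator,
    ) -> None:
        self.c_in, self.n_layers, self.growth = c_in, n_layers, growth
        self.convs, self.acts, self.drops = [], [], []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(Conv3d(c, growth, kernel, rng))
            self.acts.append(ReLU())
            self.drops.append(Dropout(dropout, rng))
            c += growth

    @property
    def c_out(self) -> int:
        return self.c_in + self.n_layers * self.growth

    def params(self) -> list[Param]:
        return [p for conv in self.convs for p in conv.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = x
        for conv, act, drop in zip(self.convs, self.acts, self.drops):
            h = drop.forward(act.forward(conv.forward(feats, train), train), train)
            feats = np.concatenate([feats, h], axis=-1)
        return feats

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dfeats = dy
        for conv, act, drop in zip(reversed(self.convs), reversed(self.acts), reversed(self.drops)):
            c_prev = dfeats.shape[-1] - self.growth
            dh = drop.backward(dfeats[..., c_prev:])
            dprev = conv.backward(act.backward(dh))
            dfeats = dfeats[..., :c_prev] + dprev
        return dfeats


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def checksum(params: list[Param]) -> str:
    """Stable digest of a parameter list (order-sensitive)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
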