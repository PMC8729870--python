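"""Minimal NumPy building blocks for small 3D convolutional networks.

Implements exactly what the desk-scale conditional GAN needs: stride-1 3D
convolutions (im2col + BLAS matmul), 2x average pooling / nearest upsampling,
leaky ReLU / tanh nonlinearities, dropout, and Adam.  Volumes are
``(batch, channels, D, H, W)`` float32 arrays.  Backward passes are exact
analytic gradients; the stride-1 choice keeps the input gradient itself a
convolution (with flipped kernels), avoiding scatter-adds.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """'Same' stride-1 3D convolution (cross-correlation), kernel k x k x k.

    Decomposed over the k^3 kernel offsets: each offset is one batched BLAS
    matmul over a contiguous slab, avoiding a full im2col copy.
    """
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    n, c, d, h, wd = x.shape
    o = w.shape[0]
    out = np.zeros((n, o, d * h * wd), dtype=DTYPE)
    for a in range(k):
        for bb in range(k):
            for g in range(k):
                slab = np.ascontiguousarray(
                    xp[:, :, a : a + d, bb : bb + h, g : g + wd]
                ).reshape(n, c, -1)
                out += w[:, :, a, bb, g] @ slab
    if b is not None:
        out += b[None, :, None]
    return out.reshape(n, o, d, h, wd)


def _conv3d_weight_grad(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """Gradient of conv3d w.r.t. the kernel: correlate input with the
    output gradient at each offset."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    n, c, d, h, wd = x.shape
    o = g.shape[1]
    gr = g.reshape(n, o, -1)
    dw = np.empty((o, c, k, k, k), dtype=DTYPE)
    for a in range(k):
        for bb in range(k):
            for gg in range(k):
                slab = np.ascontiguousarray(
                    xp[:, :, a : a + d, bb : bb + h, gg : gg + wd]
                ).reshape(n, c, -1)
                dw[:, :, a, bb, gg] = np.einsum("nos,ncs->oc", gr, slab, optimize=True)
    return dw


class Layer:
    """Base layer: forward caches what backward needs; params() exposes
    (weight, grad) pairs for the optimizer."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class Conv3d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return conv3d(x, self.w, self.b)

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dw += _conv3d_weight_grad(self._x, g, self.k)
        self.db += g.sum(axis=(0, 2, 3, 4))
        # input gradient = convolution of g with channel-swapped, flipped kernels
        wf = np.ascontiguousarray(
            self.w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        return conv3d(g, wf, None)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; the cGAN's stochastic input z.  Inactive at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class AvgPool3d(Layer):
    """2x2x2 mean pooling."""

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("pooling requires even spatial dimensions")
        self._shape = x.shape
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, g):
        g = g[:, :, :, None, :, None, :, None] / 8.0
        g = np.broadcast_to(g, g.shape[:3] + (2,) + g.shape[4:5] + (2,) + g.shape[6:7] + (2,))
        return g.reshape(self._shape)


class Upsample3d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, g):
        n, c, d, h, w = g.shape
        return g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    def __init__(self, params, lr=2e-3, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


class UNet3D:
    """Encoder-decoder with skip connections joining mirrored resolutions.

    ``depth`` pooling steps; channels double per level from ``base``.  One
    convolution per resolution level on each side, tanh output in [-1, 1].
    Dropout in the decoder realises the cGAN noise input z.
    """

    def __init__(self, depth: int, base: int, rng: np.random.Generator,
                 dropout: float = 0.3, k: int = 3, residual: bool = False):
        self.depth = depth
        #: residual mode: output = input + tanh(conv(features)).  The identity
        #: path carries the input's geometry (pose) exactly; the network only
        #: synthesises the appearance change — useful when registration-grade
        #: pose fidelity matters more than free-form synthesis.
        self.residual = residual
        self.enc: list[tuple[Conv3d, LeakyReLU]] = []
        self.pool = AvgPool3d()
        self.up = Upsample3d()
        c = 1
        chans = [base * 2**i for i in range(depth + 1)]
        for i in range(depth):
            self.enc.append((Conv3d(c, chans[i], k, rng), LeakyReLU()))
            c = chans[i]
        self.bottleneck = (Conv3d(c, chans[depth], k, rng), LeakyReLU(),
                           Dropout(dropout, rng))
        self.dec: list[tuple[Conv3d, LeakyReLU, Dropout]] = []
        c = chans[depth]
        for i in reversed(range(depth)):
            # decoder conv sees upsampled features concatenated with the skip
            self.dec.append(
                (Conv3d(c + chans[i], chans[i], k, rng), LeakyReLU(),
                 Dropout(dropout if i == depth - 1 else 0.0, rng))
            )
            c = chans[i]
        self.out_conv = Conv3d(c, 1, k, rng)
        self.out_act = Tanh()

    def _check(self, x: np.ndarray) -> None:
        for s in x.shape[2:]:
            if s % 2**self.depth:
                raise ValueError(
                    f"patch shape {x.shape[2:]} not divisible by 2^depth = {2**self.depth}"
                )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check(x)
        self._input = x
        skips = []
        self._pool_shapes = []
        for conv, act in self.enc:
            x = act.forward(conv.forward(x, train), train)
            skips.append(x)
            self._pool_shapes.append(x.shape)
            n, c, d, h, w = x.shape
            x = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))
        conv, act, drop = self.bottleneck
        x = drop.forward(act.forward(conv.forward(x, train), train), train)
        self._skip_channels = []
        for (conv, act, drop), skip in zip(self.dec, reversed(skips)):
            x = x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
            x = np.concatenate([x, skip], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = drop.forward(act.forward(conv.forward(x, train), train), train)
        out = self.out_act.forward(self.out_conv.forward(x, train), train)
        if self.residual:
            out = out + self._input
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        g_residual = g if self.residual else 0.0
        g = self.out_conv.backward(self.out_act.backward(g))
        skip_grads = []
        for (conv, act, drop), c_skip in zip(reversed(self.dec), reversed(self._skip_channels)):
            g = conv.backward(act.backward(drop.backward(g)))
            g, g_skip = g[:, :-c_skip], g[:, -c_skip:]
            skip_grads.append(g_skip)
            n, c, d, h, w = g.shape
            g = g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
        conv, act, drop = self.bottleneck
        g = conv.backward(act.backward(drop.backward(g)))
        for (conv, act), g_skip, shape in zip(
            reversed(self.enc), reversed(skip_grads), reversed(self._pool_shapes)
        ):
            gu = g[:, :, :, None, :, None, :, None] / 8.0
            gu = np.broadcast_to(
                gu, g.shape[:3] + (2, g.shape[3], 2, g.shape[4], 2)
            ).reshape(shape)
            g = conv.backward(act.backward(gu + g_skip))
        return g + g_residual

    def params(self):
        out = []
        for conv, _ in self.enc:
            out += conv.params()
        out += self.bottleneck[0].params()
        for conv, _, _ in self.dec:
            out += conv.params()
        out += self.out_conv.params()
        return out

    def state(self) -> list[np.ndarray]:
        return [w for w, _ in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for (w, _), a in zip(self.params(), arrays):
            w[...] = a.astype(DTYPE)


class PatchDiscriminator(Sequential):
    """Patch-wise real/fake classifier emitting a grid of logits.

    Two pooled levels (patch grid at 1/4 resolution) plus two extra
    convolutional layers beyond the canonical patch classifier.
    """

    def __init__(self, base: int, rng: np.random.Generator, k: int = 3):
        super().__init__(
            Conv3d(2, base, k, rng), LeakyReLU(), AvgPool3d(),
            Conv3d(base, base * 2, k, rng), LeakyReLU(), AvgPool3d(),
            Conv3d(base * 2, base * 2, k, rng), LeakyReLU(),
            Conv3d(base * 2, base * 2, k, rng), LeakyReLU(),
            Conv3d(base * 2, 1, k, rng),  # logits; sigmoid lives in the loss
        )

    def state(self) -> list[np.ndarray]:
        return [w for w, _ in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for (w, _), a in zip(self.params(), arrays):
            w[...] = a.astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))
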