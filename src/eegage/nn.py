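"""Minimal numpy neural-network core for the temporal convolutional regressor.

Implements exactly the pieces the age decoder needs — valid (unpadded)
dilated 1-D convolutions, ReLU, dropout, residual blocks, a sigmoid head,
AdamW with cosine-annealed learning rate — with hand-written backward passes.
Backprop reaches the input, which is what the amplitude-gradient saliency
analysis differentiates through.

All operations are deterministic given the numpy Generator passed in;
float32 is used throughout the training path.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1d", "ResidualBlock", "AdamW", "cosine_lr", "relu", "sigmoid"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d:
    """Valid dilated 1-D convolution: (N, C, L) -> (N, F, L - (k-1)*d)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel))
                  * math.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.kernel = kernel
        self.dilation = dilation
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None

    @property
    def span(self) -> int:
        """Input samples consumed beyond one output sample."""
        return (self.kernel - 1) * self.dilation

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        w = self.span + 1
        cols = sliding_window_view(x, w, axis=-1)[..., ::self.dilation]
        if cache:
            self._cols = cols
        y = np.einsum("nclk,fck->nfl", cols, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.gW += np.einsum("nclk,nfl->fck", cols, gy, optimize=True)
        self.gb += gy.sum(axis=(0, 2))
        n, c = cols.shape[0], cols.shape[1]
        l_in = cols.shape[2] + self.span
        gx = np.zeros((n, c, l_in), dtype=gy.dtype)
        l_out = gy.shape[2]
        for j in range(self.kernel):
            off = j * self.dilation
            gx[:, :, off:off + l_out] += np.einsum(
                "nfl,fc->ncl", gy, self.W[:, :, j], optimize=True)
        self._cols = None
        return gx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ResidualBlock:
    """Two dilated convs with ReLU + dropout, and a (possibly projected) skip.

    The skip path is trimmed at its left edge so it aligns with the shorter
    valid-convolution output (causal alignment: the block output at time t
    depends on inputs up to t).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        self.conv1 = Conv1d(in_ch, out_ch, kernel, dilation, rng)
        self.conv2 = Conv1d(out_ch, out_ch, kernel, dilation, rng)
        self.proj = Conv1d(in_ch, out_ch, 1, 1, rng) if in_ch != out_ch else None
        self.dropout = dropout
        self._caches = None

    @property
    def span(self) -> int:
        return self.conv1.span + self.conv2.span

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None, cache: bool = True) -> np.ndarray:
        a = self.conv1.forward(x, cache=cache)
        m1 = a > 0
        a = a * m1
        d1 = None
        if training and self.dropout > 0:
            d1 = (rng.random(a.shape) >= self.dropout).astype(a.dtype)
            a = a * d1 / (1.0 - self.dropout)
        b = self.conv2.forward(a, cache=cache)
        m2 = b > 0
        b = b * m2
        d2 = None
        if training and self.dropout > 0:
            d2 = (rng.random(b.shape) >= self.dropout).astype(b.dtype)
            b = b * d2 / (1.0 - self.dropout)
        trim = self.span
        skip_in = x[:, :, trim:]
        if self.proj is not None:
            skip = self.proj.forward(skip_in, cache=cache)
        else:
            skip = skip_in
        if cache:
            self._caches = (m1, d1, m2, d2, x.shape)
        return b + skip

    def backward(self, gy: np.ndarray) -> np.ndarray:
        m1, d1, m2, d2, x_shape = self._caches
        gb = gy
        if d2 is not None:
            gb = gb * d2 / (1.0 - self.dropout)
        gb = gb * m2
        ga = self.conv2.backward(gb)
        if d1 is not None:
            ga = ga * d1 / (1.0 - self.dropout)
        ga = ga * m1
        gx = self.conv1.backward(ga)
        if self.proj is not None:
            gskip = self.proj.backward(gy)
        else:
            gskip = gy
        gx[:, :, self.span:] += gskip
        self._caches = None
        return gx

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class AdamW:
    """AdamW (decoupled weight decay), operating on (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def cosine_lr(step: int, total_steps: int, lr_max: float,
              lr_min: float = 0.0) -> float:
    """Cosine annealing from lr_max to lr_min over total_steps."""
    if total_steps <= 1:
        return lr_max
    frac = min(step / (total_steps - 1), 1.0)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))
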