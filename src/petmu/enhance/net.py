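"""A compact N-dimensional U-Net in plain numpy, with manual backprop.

Supports 2-D and 3-D inputs. Building blocks: 3^d "same" convolutions with
channel-wise PReLU activations, 2x average-pool downsampling, nearest
upsampling, skip concatenation, and a global residual connection (the
network predicts a correction to its input, which is the natural
parameterisation for mu-map enhancement). Training uses Adam on mean
absolute error by default. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from ..core import ValidationError


def _he_init(rng: np.random.Generator, shape, fan_in: float) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ConvNd:
    """3^d same-padding convolution over (batch, channels, *spatial)."""

    def __init__(self, rng, c_in: int, c_out: int, ndim: int, ksize: int = 3):
        self.ndim = ndim
        self.k = ksize
        kshape = (c_out, c_in) + (ksize,) * ndim
        self.W = _he_init(rng, kshape, c_in * ksize ** ndim)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._spec_fwd = {2: "bchwij,ocij->bohw", 3: "bcdhwijk,ocijk->bodhw"}[ndim]
        self._spec_dw = {2: "bchwij,bohw->ocij", 3: "bcdhwijk,bodhw->ocijk"}[ndim]

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        pad = ((0, 0), (0, 0)) + ((p, p),) * self.ndim
        xp = np.pad(x, pad)
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k,) * self.ndim, axis=tuple(range(2, 2 + self.ndim)))
        self._win = win
        self._xshape = x.shape
        y = np.einsum(self._spec_fwd, win, self.W, optimize=True)
        return y + self.b.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, dy: np.ndarray):
        self.dW = np.einsum(self._spec_dw, self._win, dy, optimize=True)
        self.db = dy.sum(axis=tuple(i for i in range(dy.ndim) if i != 1))
        p = self.k // 2
        spatial = self._xshape[2:]
        dxp = np.zeros((dy.shape[0], self.W.shape[1])
                       + tuple(s + 2 * p for s in spatial), dtype=np.float32)
        # scatter each kernel offset back: dX[.., i:i+H, ..] += dY * W[..,i,..]
        for off in np.ndindex(*(self.k,) * self.ndim):
            w_off = self.W[(slice(None), slice(None)) + off]  # (c_out, c_in)
            contrib = np.einsum("bo...,oc->bc...", dy, w_off, optimize=True)
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            dxp[sl] += contrib
        unpad = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for s in spatial)
        self._win = None
        return dxp[unpad]

    @property
    def grads(self):
        return [self.dW, self.db]


class PReLU:
    """Channel-wise parametric rectified linear activation."""

    def __init__(self, channels: int, init: float = 0.25):
        self.a = np.full(channels, init, dtype=np.float32)

    @property
    def params(self):
        return [self.a]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = self.a.reshape((1, -1) + (1,) * (x.ndim - 2))
        return np.where(x > 0, x, a * x)

    def backward(self, dy: np.ndarray):
        x = self._x
        a = self.a.reshape((1, -1) + (1,) * (x.ndim - 2))
        neg = x <= 0
        axes = tuple(i for i in range(x.ndim) if i != 1)
        self.da = np.sum(dy * x * neg, axis=axes)
        self._x = None
        return np.where(neg, a * dy, dy)

    @property
    def grads(self):
        return [self.da]


class AvgPool:
    """Factor-2 average pooling along each spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        if any(s % 2 for s in x.shape[2:]):
            raise ValidationError("spatial sizes must be even for pooling")
        self._shape = x.shape
        out = x
        for ax in range(2, 2 + nd):
            s = out.shape
            out = out.reshape(s[:ax] + (s[ax] // 2, 2) + s[ax + 1:]).mean(axis=ax + 1)
        return out

    def backward(self, dy: np.ndarray):
        nd = dy.ndim - 2
        out = dy / (2 ** nd)
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    params = ()
    grads = ()


class Upsample:
    """Nearest-neighbour factor-2 upsampling (adjoint: block sum)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        out = x
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, dy: np.ndarray):
        nd = dy.ndim - 2
        out = dy
        for ax in range(2, 2 + nd):
            s = out.shape
            out = out.reshape(s[:ax] + (s[ax] // 2, 2) + s[ax + 1:]).sum(axis=ax + 1)
        return out

    params = ()
    grads = ()


class _Block:
    """Two conv + PReLU stages."""

    def __init__(self, rng, c_in, c_out, ndim):
        self.layers = [ConvNd(rng, c_in, c_out, ndim), PReLU(c_out),
                       ConvNd(rng, c_out, c_out, ndim), PReLU(c_out)]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the enhancement network.

    ``levels`` counts down-sampling (and matching up-sampling) stages; patch
    sizes must be divisible by ``2**levels``. The default mirrors a deep
    five-level encoder-decoder with 64-per-axis patches; reduced settings
    are appropriate for small 2-D problems.
    """

    levels: int = 5
    base_channels: int = 16
    patch_size: int = 64
    ndim: int = 2
    max_channel_factor: int = 4

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise ValidationError("ndim must be 2 or 3")
        if self.patch_size % (2 ** self.levels):
            raise ValidationError(
                f"patch_size {self.patch_size} not divisible by 2^levels")

    def channels_at(self, level: int) -> int:
        return self.base_channels * min(2 ** level, self.max_channel_factor)


class UNet:
    """Encoder-decoder with skip connections and a global residual."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        nd = cfg.ndim
        self.enc = []
        c_prev = 1
        for lv in range(cfg.levels):
            c = cfg.channels_at(lv)
            self.enc.append(_Block(rng, c_prev, c, nd))
            c_prev = c
        self.bottom = _Block(rng, c_prev, cfg.channels_at(cfg.levels), nd)
        self.dec = []
        c_prev = cfg.channels_at(cfg.levels)
        for lv in reversed(range(cfg.levels)):
            c_skip = cfg.channels_at(lv)
            self.dec.append(_Block(rng, c_prev + c_skip, c_skip, nd))
            c_prev = c_skip
        self.out_conv = ConvNd(rng, c_prev, 1, nd, ksize=1)
        self.pool = AvgPool()
        self.up = Upsample()

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        for blk in self.enc + [self.bottom] + self.dec:
            yield from blk.layers
        yield self.out_conv

    @property
    def params(self) -> List[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.params)
        return out

    @property
    def grads(self) -> List[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.grads)
        return out

    def state_arrays(self) -> List[np.ndarray]:
        return self.params

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.params
        if len(arrays) != len(params):
            raise ValidationError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValidationError("checkpoint shape mismatch")
            p[...] = a

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, 1, *spatial) -> same shape."""
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            skips.append(h)
            h = self.pool.forward(h)
        h = self.bottom.forward(h)
        self._cats = []
        for blk, skip in zip(self.dec, reversed(skips)):
            h = self.up.forward(h)
            c_up = h.shape[1]
            h = np.concatenate([h, skip], axis=1)
            self._cats.append(c_up)
            h = blk.forward(h)
        return x + self.out_conv.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.out_conv.backward(dy)
        dskips = []
        for blk, c_up in zip(reversed(self.dec), reversed(self._cats)):
            dh = blk.backward(dh)
            d_up, d_skip = dh[:, :c_up], dh[:, c_up:]
            dskips.append(d_skip)
            dh = self.up.backward(d_up)
        dh = self.bottom.backward(dh)
        for blk, d_skip in zip(reversed(self.enc), reversed(dskips)):
            dh = self.pool.backward(dh)
            dh = blk.backward(dh + d_skip)
        return dh + dy  # global residual


class Adam:
    """Adaptive-moment optimiser over a parameter list (in-place updates)."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its gradient."""
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float((diff ** 2).mean()), 2.0 * diff / diff.size


LOSSES = {"mae": mae_loss, "mse": mse_loss}
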