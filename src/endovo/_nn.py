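"""Minimal numpy neural-network kit: 3x3 convolutions, pooling,
nearest upsampling, ReLU/sigmoid, a 3-level UNet and Adam.

Forward passes cache activations on the instance; ``backward`` consumes
the cache of the immediately preceding forward call and returns
parameter gradients (input gradients are propagated internally).  All
convolutions are implemented with strided window views + tensordot,
which is fast enough for the small training resolutions this package
uses on a CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet3", "Adam"]


def _conv_forward(x, w, b):
    """x: (C, H, W); w: (F, C, 3, 3) -> (F, H, W), zero padding."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    return np.tensordot(w, win, axes=((1, 2, 3), (0, 3, 4))) + b[:, None, None]


def _conv_backward(x, w, dy):
    """Gradients of a 3x3 same-conv: returns (dx, dw, db)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))
    dw = np.tensordot(dy, win, axes=((1, 2), (1, 2)))  # (F, C, 3, 3)
    db = dy.sum(axis=(1, 2))
    wflip = w[:, :, ::-1, ::-1]
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dyp, (3, 3), axis=(1, 2))  # (F, H, W, 3, 3)
    dx = np.tensordot(wflip, dwin, axes=((0, 2, 3), (0, 3, 4)))
    return dx, dw, db


def _conv1x1_forward(x, w, b):
    return np.tensordot(w[:, :, 0, 0], x, axes=(1, 0)) + b[:, None, None]


def _conv1x1_backward(x, w, dy):
    dw = np.tensordot(dy, x, axes=((1, 2), (1, 2)))[:, :, None, None]
    db = dy.sum(axis=(1, 2))
    dx = np.tensordot(w[:, :, 0, 0].T, dy, axes=(1, 0))
    return dx, dw, db


def _pool2(x):
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _pool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(dy):
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class UNet3:
    """3-resolution-level encoder-decoder with skip connections.

    Two 3x3 conv + ReLU blocks per level, 2x average-pool downsampling,
    nearest-neighbour upsampling, a final 1x1 convolution and a sigmoid
    so the output map lies in [0, 1].  Channel width doubles per level.
    Inputs of arbitrary spatial size are zero-padded to a multiple of 4
    and the output cropped back.
    """

    def __init__(self, in_channels: int, base_channels: int = 16, rng=None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.base_channels = base_channels
        c1, c2, c3 = base_channels, 2 * base_channels, 4 * base_channels
        spec = {
            "c1a": (c1, in_channels, 3),
            "c1b": (c1, c1, 3),
            "c2a": (c2, c1, 3),
            "c2b": (c2, c2, 3),
            "c3a": (c3, c2, 3),
            "c3b": (c3, c3, 3),
            "c4a": (c2, c3 + c2, 3),
            "c4b": (c2, c2, 3),
            "c5a": (c1, c2 + c1, 3),
            "c5b": (c1, c1, 3),
            "out": (1, c1, 1),
        }
        self.params: dict[str, np.ndarray] = {}
        for name, (fout, fin, k) in spec.items():
            scale = np.sqrt(2.0 / (fin * k * k))
            if name == "out":
                scale *= 0.1  # start close to the sigmoid midpoint 0.5
            self.params[f"{name}.w"] = rng.normal(0.0, scale, size=(fout, fin, k, k))
            self.params[f"{name}.b"] = np.zeros(fout)
        self._cache = None

    # ------------------------------------------------------------------
    def _block(self, x, name, cache):
        w, b = self.params[f"{name}.w"], self.params[f"{name}.b"]
        z = _conv_forward(x, w, b)
        a = np.maximum(z, 0.0)
        cache[name] = (x, z)
        return a

    def _block_back(self, da, name, cache, grads):
        x, z = cache[name]
        dz = da * (z > 0)
        dx, dw, db = _conv_backward(x, self.params[f"{name}.w"], dz)
        grads[f"{name}.w"] = dw
        grads[f"{name}.b"] = db
        return dx

    def forward(self, stack: np.ndarray) -> np.ndarray:
        """stack: (C, H, W) -> weight map (H, W) in [0, 1]."""
        c, h, w = stack.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        ph, pw = (-h) % 4, (-w) % 4
        x = np.pad(stack, ((0, 0), (0, ph), (0, pw)))
        cache: dict = {"shape": (h, w), "pad": (ph, pw)}

        a1 = self._block(self._block(x, "c1a", cache), "c1b", cache)
        a2 = self._block(self._block(_pool2(a1), "c2a", cache), "c2b", cache)
        a3 = self._block(self._block(_pool2(a2), "c3a", cache), "c3b", cache)
        u2 = np.concatenate([_up2(a3), a2], axis=0)
        a4 = self._block(self._block(u2, "c4a", cache), "c4b", cache)
        u1 = np.concatenate([_up2(a4), a1], axis=0)
        a5 = self._block(self._block(u1, "c5a", cache), "c5b", cache)
        z = _conv1x1_forward(a5, self.params["out.w"], self.params["out.b"])
        if not np.all(np.isfinite(z)):
            raise FloatingPointError("non-finite activations in weight network")
        y = 1.0 / (1.0 + np.exp(-z[0]))
        cache["a5"] = a5
        cache["y"] = y
        cache["ch"] = (a3.shape[0], a4.shape[0])
        self._cache = cache
        return y[:h, :w]

    def backward(self, dy: np.ndarray) -> dict:
        """Parameter gradients for the loss gradient ``dy`` (H, W)."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before forward")
        h, w = cache["shape"]
        ph, pw = cache["pad"]
        y = cache["y"]
        dyp = np.zeros_like(y)
        dyp[:h, :w] = dy
        dz = (dyp * y * (1.0 - y))[None]
        grads: dict = {}
        da5, grads["out.w"], grads["out.b"] = _conv1x1_backward(
            cache["a5"], self.params["out.w"], dz
        )
        du1 = self._block_back(self._block_back(da5, "c5b", cache, grads), "c5a", cache, grads)
        c3n, c2n = cache["ch"]
        da4 = _up2_backward(du1[: du1.shape[0] - self.base_channels])
        da1 = du1[du1.shape[0] - self.base_channels :]
        du2 = self._block_back(self._block_back(da4, "c4b", cache, grads), "c4a", cache, grads)
        da3 = _up2_backward(du2[:c3n])
        da2 = du2[c3n:]
        dp2 = self._block_back(self._block_back(da3, "c3b", cache, grads), "c3a", cache, grads)
        da2 = da2 + _pool2_backward(dp2)
        dp1 = self._block_back(self._block_back(da2, "c2b", cache, grads), "c2a", cache, grads)
        da1 = da1 + _pool2_backward(dp1)
        self._block_back(self._block_back(da1, "c1b", cache, grads), "c1a", cache, grads)
        self._cache = None
        return grads

    # ------------------------------------------------------------------
    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict):
        for k in self.params:
            self.params[k] = params[k].copy()


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m.get(k, 0.0) + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v.get(k, 0.0) + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
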