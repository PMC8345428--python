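"""Numpy neural-network layers with forward and backward passes.

Activations are ``float32`` arrays laid out ``(C, H, W)``; the training
convention is one full tile per step, so there is no batch axis.
Convolutions are im2col + BLAS GEMM; the transposed convolution is the
exact adjoint of a strided convolution, computed by scatter-adding GEMM
output over kernel offsets.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameters and gradients are name-keyed dicts."""

    def __init__(self, name: str):
        self.name = name
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ZeroPad(Layer):
    def __init__(self, name: str, pad: int):
        super().__init__(name)
        self.pad = pad

    def forward(self, x, train=False):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p)))

    def backward(self, dy):
        p = self.pad
        return dy[:, p:dy.shape[1] - p, p:dy.shape[2] - p]


class Conv2D(Layer):
    """k×k stride-1 convolution (cross-correlation) with optional zero pad."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, pad: int = 0,
                 bias: bool = True):
        super().__init__(name)
        self.c_in, self.c_out, self.k, self.pad = c_in, c_out, k, pad
        self.params["W"] = np.zeros((c_out, c_in, k, k), dtype=np.float32)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: Optional[np.ndarray] = None
        self._in_hw = (0, 0)

    def forward(self, x, train=False):
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p)))
        c, hp, wp = x.shape
        ho, wo = hp - k + 1, wp - k + 1
        if ho <= 0 or wo <= 0:
            raise ValueError(f"{self.name}: input {hp}x{wp} too small for k={k}")
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (C,Ho,Wo,k,k)
        cols = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(
            ho * wo, c * k * k)
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"]
        self._cols = cols if train else None
        self._in_hw = (hp, wp)
        return np.ascontiguousarray(out.reshape(ho, wo, self.c_out).transpose(2, 0, 1))

    def backward(self, dy):
        k, p = self.k, self.pad
        c_out, ho, wo = dy.shape
        dym = dy.reshape(c_out, ho * wo).T  # (Ho*Wo, Cout)
        self.grads["W"] = (dym.T @ self._cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(1, 2))
        wmat = self.params["W"].reshape(self.c_out, -1)
        dcols = dym @ wmat  # (Ho*Wo, Cin*k*k)
        hp, wp = self._in_hw
        dxp = np.zeros((self.c_in, hp, wp), dtype=np.float32)
        dwin = dcols.reshape(ho, wo, self.c_in, k, k)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + ho, kj:kj + wo] += dwin[:, :, :, ki, kj].transpose(2, 0, 1)
        self._cols = None
        if p:
            return dxp[:, p:hp - p, p:wp - p]
        return dxp


class ReLU(Layer):
    def __init__(self, name: str):
        super().__init__(name)
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2Ceil(Layer):
    """2×2 stride-2 max pooling, output size rounded up on odd inputs."""

    def __init__(self, name: str):
        super().__init__(name)
        self._argmax = None
        self._in_hw = (0, 0)

    def forward(self, x, train=False):
        c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        hp, wp = x.shape[1], x.shape[2]
        ho, wo = hp // 2, wp // 2
        windows = x.reshape(c, ho, 2, wo, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, ho, wo, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax = idx
            self._in_hw = (h, w)
        return out

    def backward(self, dy):
        c, ho, wo = dy.shape
        flat = np.zeros((c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dxp = flat.reshape(c, ho, wo, 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, ho * 2, wo * 2)
        h, w = self._in_hw
        return dxp[:, :h, :w]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, name: str, p: float):
        super().__init__(name)
        self.p = p
        self.rng: Optional[np.random.Generator] = None
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError(f"{self.name}: no RNG bound for training")
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class ConvTranspose2D(Layer):
    """Transposed convolution: output size ``(H-1)·stride + k``."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, stride: int,
                 bias: bool = False):
        super().__init__(name)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.params["W"] = np.zeros((c_in, c_out, k, k), dtype=np.float32)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x = None

    def forward(self, x, train=False):
        c_in, h, w = x.shape
        k, s = self.k, self.stride
        ho, wo = (h - 1) * s + k, (w - 1) * s + k
        xmat = x.reshape(c_in, h * w)
        wmat = self.params["W"].reshape(c_in, self.c_out * k * k)
        cols = (wmat.T @ xmat).reshape(self.c_out, k, k, h, w)
        out = np.zeros((self.c_out, ho, wo), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                out[:, ki:ki + (h - 1) * s + 1:s,
                    kj:kj + (w - 1) * s + 1:s] += cols[:, ki, kj]
        if "b" in self.params:
            out += self.params["b"][:, None, None]
        self._x = x if train else None
        self._in_hw = (h, w)
        return out

    def backward(self, dy):
        k, s = self.k, self.stride
        h, w = self._in_hw
        dcols = np.empty((self.c_out, k, k, h, w), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dcols[:, ki, kj] = dy[:, ki:ki + (h - 1) * s + 1:s,
                                      kj:kj + (w - 1) * s + 1:s]
        dcols_mat = dcols.reshape(self.c_out * k * k, h * w)
        wmat = self.params["W"].reshape(self.c_in, self.c_out * k * k)
        dx = (wmat @ dcols_mat).reshape(self.c_in, h, w)
        xmat = self._x.reshape(self.c_in, h * w)
        self.grads["W"] = (xmat @ dcols_mat.T).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(1, 2))
        self._x = None
        return dx


class CenterCrop(Layer):
    """Crop ``offset`` pixels from each side, down to ``out_px`` squares."""

    def __init__(self, name: str, offset: int, out_px: int):
        super().__init__(name)
        self.offset = offset
        self.out_px = out_px
        self._in_hw = (0, 0)

    def forward(self, x, train=False):
        o, n = self.offset, self.out_px
        c, h, w = x.shape
        if o + n > h or o + n > w:
            raise ValueError(
                f"{self.name}: cannot crop {n}+{o} from {h}x{w}")
        self._in_hw = (h, w)
        return x[:, o:o + n, o:o + n]

    def backward(self, dy):
        h, w = self._in_hw
        dx = np.zeros((dy.shape[0], h, w), dtype=np.float32)
        o, n = self.offset, self.out_px
        dx[:, o:o + n, o:o + n] = dy
        return dx


def bilinear_upsample_kernel(k: int, dtype=np.float32) -> np.ndarray:
    """The separable 2-D bilinear interpolation kernel of side ``k``.

    For an even kernel (the stride-32 / kernel-64 case) the center sits at
    ``k/2 - 0.5`` and the triangular profile has half-width ``k/2``.
    """
    factor = (k + 1) // 2
    center = factor - 1.0 if k % 2 == 1 else factor - 0.5
    og = np.arange(k, dtype=np.float64)
    w1d = 1.0 - np.abs(og - center) / factor
    return np.outer(w1d, w1d).astype(dtype)
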