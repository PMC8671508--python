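"""Minimal CNN machinery: 2D convolution, batch norm, ReLU, Adam, MSE.

Implements exactly what the EMI canceller needs, in float32 NumPy with
im2col + BLAS GEMM so a per-scan training run fits in minutes on one CPU
core.  Layout is channels-last (B, H, W, C), matching the canceller's
native example shape (n_x samples x 10 coils x 2 real/imag channels).

Convolutions use stride 1 and zero same-padding (odd kernels), so spatial
shape is preserved through the network.  The input-gradient pass is itself a
same-padded convolution with the spatially flipped, transposed kernel, which
keeps every heavy operation a single GEMM.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Sequential", "Adam",
           "mse_loss", "mse_grad"]

F32 = np.float32


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, kh*kw*C) patch matrix with same-padding."""
    B, H, W, C = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # (B, H, W, C, kh, kw) -> (B, H, W, kh, kw, C); C contiguous in source
    return v.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, kh * kw * C)


def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if (ph or pw) else x


def _conv_shift(xp: np.ndarray, w: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Convolution as kh*kw shifted-slice GEMM accumulations.

    ``xp`` is the padded input (B, Hp, Wp, C); ``w`` is (kh, kw, C, F).
    Faster than im2col when C is large (slice copies have long contiguous
    runs and every GEMM keeps the full K = C dimension).
    """
    B = xp.shape[0]
    H, W = out_hw
    kh, kw, C, F = w.shape
    y = np.zeros((B * H * W, F), dtype=F32)
    for u in range(kh):
        for v in range(kw):
            sl = np.ascontiguousarray(xp[:, u:u + H, v:v + W, :]).reshape(-1, C)
            y += sl @ w[u, v]
    return y.reshape(B, H, W, F)


def _conv_shift_dw(xp: np.ndarray, dy_flat: np.ndarray, kh: int, kw: int,
                   out_hw: tuple[int, int]) -> np.ndarray:
    B, C = xp.shape[0], xp.shape[3]
    H, W = out_hw
    F = dy_flat.shape[1]
    dw = np.empty((kh, kw, C, F), dtype=F32)
    for u in range(kh):
        for v in range(kw):
            sl = np.ascontiguousarray(xp[:, u:u + H, v:v + W, :]).reshape(-1, C)
            dw[u, v] = sl.T @ dy_flat
    return dw


class Conv2d:
    """Same-padded stride-1 convolution; weights (kh, kw, c_in, c_out).

    Each of the forward, weight-gradient and input-gradient passes is GEMM
    based, via im2col patches when the contracted channel count is small and
    via shifted-slice accumulation when it is large.
    """

    _SHIFT_MIN_CHANNELS = 48

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding requires odd kernel sizes")
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan_in = kh * kw * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kh, kw, c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._fwd_shift = c_in >= self._SHIFT_MIN_CHANNELS
        self._cols: Optional[np.ndarray] = None
        self._xp: Optional[np.ndarray] = None
        self._xshape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, _ = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        if self._fwd_shift:
            xp = _pad_hw(x, ph, pw)
            y = _conv_shift(xp, self.W, (H, W))
            if train:
                self._xp, self._xshape = xp, x.shape
        else:
            cols = _im2col(x, self.kh, self.kw)
            y = (cols @ self.W.reshape(-1, self.c_out)).reshape(B, H, W, self.c_out)
            if train:
                self._cols, self._xshape = cols, x.shape
        y += self.b
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> Optional[np.ndarray]:
        B, H, W, _ = dy.shape
        dy_flat = np.ascontiguousarray(dy).reshape(B * H * W, self.c_out)
        if self._fwd_shift:
            self.dW = _conv_shift_dw(self._xp, dy_flat, self.kh, self.kw, (H, W))
            self._xp = None
        else:
            self.dW = (self._cols.T @ dy_flat).reshape(self.W.shape)
            self._cols = None
        self.db = dy_flat.sum(axis=0)
        if not need_dx:
            return None
        # dx = same-padded conv of dy with the flipped, in/out-swapped kernel
        w_flip = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        ph, pw = self.kh // 2, self.kw // 2
        if self.c_out >= self._SHIFT_MIN_CHANNELS:
            dx = _conv_shift(_pad_hw(dy, ph, pw), w_flip, (H, W))
        else:
            cols_dy = _im2col(dy, self.kh, self.kw)
            dx = (cols_dy @ w_flip.reshape(-1, self.c_in)).reshape(self._xshape)
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics at inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._xhat: Optional[np.ndarray] = None
        self._istd: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * istd
        if train:
            self._xhat, self._istd = xhat, istd.astype(F32)
        return (self.gamma * xhat + self.beta).astype(F32, copy=False)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.dgamma = np.sum(dy * xhat, axis=(0, 1, 2))
        self.dbeta = np.sum(dy, axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = istd * (dxhat - dxhat.mean(axis=(0, 1, 2))
                     - xhat * (dxhat * xhat).mean(axis=(0, 1, 2)))
        self._xhat = self._istd = None
        return dx.astype(F32, copy=False)

    def params(self):
        return [("gamma", self), ("beta", self)]


class ReLU:
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, F32(0.0))
        return np.maximum(x, F32(0.0))

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        dx = np.where(self._mask, dy, F32(0.0))
        self._mask = None
        return dx

    def params(self):
        return []


class Sequential:
    def __init__(self, layers: Sequence) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate; the input gradient of the first layer is skipped."""
        for i in range(len(self.layers) - 1, -1, -1):
            dy = self.layers[i].backward(dy, need_dx=(i > 0))

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all learnable and running state."""
        out = {}
        for i, layer in enumerate(self.layers):
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    out[f"layer{i}/{attr}"] = getattr(layer, attr)
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, val in state.items():
            idx, attr = key.split("/")
            setattr(self.layers[int(idx.removeprefix("layer"))], attr,
                    np.asarray(val, dtype=F32))


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, net: Sequential, lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, layer in self.net.params():
            key = (id(layer), name)
            g = getattr(layer, "d" + name)
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p = getattr(layer, name)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    d = pred - target
    return float(np.mean(d.astype(np.float64) ** 2))


def mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return (2.0 / pred.size) * (pred - target)
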