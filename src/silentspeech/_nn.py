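"""Minimal numpy neural-network core: 1-D conv blocks, dense layers,
L2-normalized embeddings, and Adam.

Layers follow a forward(x) -> (y, cache) / backward(cache, dy) -> dx
convention; parameter gradients accumulate into ``Param.grad`` so the two
branches of a Siamese pair can share weights simply by being the same
objects. Everything is float64 and CPU-only; sizes in this package are
small enough that im2col-style einsum convolutions are fast.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "_m", "_v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self._m = np.zeros_like(self.value)
        self._v = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv1d:
    """Same-padded 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        assert kernel_size % 2 == 1
        self.k = kernel_size
        self.pad = (kernel_size - 1) // 2
        scale = np.sqrt(2.0 / (c_in * kernel_size))  # He init for ReLU nets
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel_size)))
        self.b = Param(np.zeros(c_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        # x: (B, C_in, L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.k, axis=2)  # (B, C_in, L, k)
        y = np.einsum("bclk,ock->bol", win, self.W.value, optimize=True)
        y += self.b.value[None, :, None]
        return y, (win, x.shape)

    def backward(self, cache: tuple, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        win, x_shape = cache
        self.W.grad += np.einsum("bol,bclk->ock", dy, win, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2))
        if not need_dx:
            return None
        B, C, L = x_shape
        dxp = np.zeros((B, C, L + 2 * self.pad))
        for j in range(self.k):
            # contribution of kernel tap j to padded-input position l + j
            dxp[:, :, j : j + L] += np.einsum("bol,oc->bcl", dy, self.W.value[:, :, j], optimize=True)
        return dxp[:, :, self.pad : self.pad + L]


class ReLU:
    @staticmethod
    def forward(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mask = x > 0
        return x * mask, mask

    @staticmethod
    def backward(mask: np.ndarray, dy: np.ndarray) -> np.ndarray:
        return dy * mask


class AvgPool2:
    """Average pooling, width 2 stride 2 (odd tails are dropped)."""

    @staticmethod
    def forward(x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        L = x.shape[-1]
        Lt = L - (L % 2)
        xt = x[..., :Lt]
        y = 0.5 * (xt[..., ::2] + xt[..., 1::2])
        return y, (L,)

    @staticmethod
    def backward(cache: tuple, dy: np.ndarray) -> np.ndarray:
        (L,) = cache
        dx = np.zeros(dy.shape[:-1] + (L,))
        dx[..., : 2 * dy.shape[-1] : 2] = 0.5 * dy
        dx[..., 1 : 2 * dy.shape[-1] : 2] = 0.5 * dy
        return dx


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return x @ self.W.value.T + self.b.value, x

    def backward(self, x: np.ndarray, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


def l2_normalize(x: np.ndarray, eps: float = 1e-12) -> Tuple[np.ndarray, tuple]:
    norm = np.linalg.norm(x, axis=-1, keepdims=True)
    norm = np.maximum(norm, eps)
    y = x / norm
    return y, (y, norm)


def l2_normalize_backward(cache: tuple, dy: np.ndarray) -> np.ndarray:
    y, norm = cache
    proj = np.sum(y * dy, axis=-1, keepdims=True)
    return (dy - y * proj) / norm


class ConvStack:
    """n blocks of (Conv1d k, ReLU, AvgPool2) followed by global average
    pooling: maps (B, C_in, L) -> (B, C_last) features."""

    def __init__(self, c_in: int, channels: Sequence[int], kernel_size: int,
                 rng: np.random.Generator):
        self.convs: List[Conv1d] = []
        prev = c_in
        for c in channels:
            self.convs.append(Conv1d(prev, c, kernel_size, rng))
            prev = c
        self.out_channels = prev

    def params(self) -> List[Param]:
        return [p for conv in self.convs for p in conv.params()]

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, list]:
        caches = []
        for conv in self.convs:
            x, c_cache = conv.forward(x)
            x, mask = ReLU.forward(x)
            x, p_cache = AvgPool2.forward(x)
            caches.append((c_cache, mask, p_cache))
        L_final = x.shape[-1]
        feat = x.mean(axis=-1)  # global average pool -> (B, C)
        caches.append(L_final)
        return feat, caches

    def backward(self, caches: list, dfeat: np.ndarray) -> None:
        L_final = caches[-1]
        dx = np.repeat(dfeat[:, :, None], L_final, axis=2) / L_final
        for i in range(len(self.convs) - 1, -1, -1):
            c_cache, mask, p_cache = caches[i]
            dx = AvgPool2.backward(p_cache, dx)
            dx = ReLU.backward(mask, dx)
            dx = self.convs[i].backward(c_cache, dx, need_dx=(i > 0))


class Adam:
    def __init__(self, params: List[Param], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p._m = b1 * p._m + (1 - b1) * p.grad
            p._v = b2 * p._v + (1 - b2) * p.grad ** 2
            m_hat = p._m / (1 - b1 ** self.t)
            v_hat = p._v / (1 - b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
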