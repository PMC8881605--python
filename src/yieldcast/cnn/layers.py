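"""Minimal numpy layer primitives: 1-D convolution (valid padding), average
pooling, dense layers, ReLU and the Adam update. Shapes follow the
(N, length, channels) convention for sequence tensors."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(grad: np.ndarray, pre_activation: np.ndarray) -> np.ndarray:
    return grad * (pre_activation > 0.0)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int, stride: int):
    """Valid 1-D convolution.

    x: (N, L, Cin); w: (kernel * Cin, F); b: (F,).
    Returns (y, cols) with y: (N, Lout, F) and the im2col cache.
    """
    windows = sliding_window_view(x, kernel, axis=1)  # (N, L-k+1, Cin, k)
    windows = windows[:, ::stride]
    cols = windows.transpose(0, 1, 3, 2).reshape(x.shape[0], windows.shape[1], -1)
    y = cols @ w + b
    return y, cols


def conv1d_backward(grad: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray, kernel: int, stride: int):
    """Gradients for conv1d_forward; returns (dx, dw, db)."""
    n, l_out, f = grad.shape
    dw = cols.reshape(-1, cols.shape[-1]).T @ grad.reshape(-1, f)
    db = grad.sum(axis=(0, 1))
    dcols = (grad @ w.T).reshape(n, l_out, kernel, -1)
    dx = np.zeros(x_shape)
    for i in range(kernel):
        dx[:, i : i + l_out * stride : stride, :] += dcols[:, :, i, :]
    return dx, dw, db


def avgpool1d_forward(x: np.ndarray, width: int):
    """Non-overlapping average pooling; a trailing remainder is dropped."""
    n, l, c = x.shape
    l_out = l // width
    y = x[:, : l_out * width, :].reshape(n, l_out, width, c).mean(axis=2)
    return y, l

def avgpool1d_backward(grad: np.ndarray, width: int, input_length: int) -> np.ndarray:
    n, l_out, c = grad.shape
    dx = np.zeros((n, input_length, c))
    dx[:, : l_out * width, :] = np.repeat(grad / width, width, axis=1)
    return dx


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return x @ w + b


def dense_backward(grad: np.ndarray, x: np.ndarray, w: np.ndarray):
    return grad @ w.T, x.T @ grad, grad.sum(axis=0)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
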