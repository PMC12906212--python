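"""Minimal dense/conv building blocks with manual gradients.

The trainable networks in this package are tiny (at most a few thousand
parameters, ~120 training frames), so forward/backward passes are written
directly in numpy and optimised with Adam. Conventions: inputs are batched
along axis 0; dense weights have shape (n_in, n_out).
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    w = weights[labels]
    loss = float(-(w * np.log(p[np.arange(n), labels] + 1e-12)).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 2-D correlation. x: (B,H,W,Cin), w: (kh,kw,Cin,Cout), b: (Cout,)."""
    kh, kw = w.shape[:2]
    B, H, W, _ = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    out = np.tile(b, (B, Ho, Wo, 1))
    for u in range(kh):
        for v in range(kw):
            out += x[:, u:u + Ho, v:v + Wo, :] @ w[u, v]
    return out


def conv2d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    kh, kw = w.shape[:2]
    Ho, Wo = dout.shape[1:3]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for u in range(kh):
        for v in range(kw):
            patch = x[:, u:u + Ho, v:v + Wo, :]
            dw[u, v] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dx[:, u:u + Ho, v:v + Wo, :] += dout @ w[u, v].T
    db = dout.sum(axis=(0, 1, 2))
    return dx, dw, db


def maxpool_forward(x: np.ndarray, size: int, stride: int):
    """Ceil-mode max pooling (partial edge windows kept)."""
    B, H, W, C = x.shape
    Ho = -(-H // stride)
    Wo = -(-W // stride)
    out = np.empty((B, Ho, Wo, C))
    argmask = np.zeros_like(x, dtype=bool)
    idx = []  # per-window slices for backward
    for i in range(Ho):
        for j in range(Wo):
            rs = slice(i * stride, min(i * stride + size, H))
            cs = slice(j * stride, min(j * stride + size, W))
            win = x[:, rs, cs, :]
            out[:, i, j, :] = win.max(axis=(1, 2))
            idx.append((rs, cs))
    return out, idx


def maxpool_backward(x: np.ndarray, out: np.ndarray, idx, dout: np.ndarray):
    dx = np.zeros_like(x)
    Ho, Wo = out.shape[1:3]
    k = 0
    for i in range(Ho):
        for j in range(Wo):
            rs, cs = idx[k]
            k += 1
            win = x[:, rs, cs, :]
            mask = win == out[:, i, j, :][:, None, None, :]
            # split gradient across ties to keep backward deterministic
            mask = mask / np.maximum(mask.sum(axis=(1, 2), keepdims=True), 1)
            dx[:, rs, cs, :] += mask * dout[:, i, j, :][:, None, None, :]
    return dx
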