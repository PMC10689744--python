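"""Minimal numpy neural-network layers with manual backprop and Adam.

Supports exactly what the spectral-spatial residual classifier needs:
pointwise (1x1) dense maps over patch pixels, 3x3 spatial convolution with
reflect padding, residual composition, average pooling and softmax
cross-entropy. Everything is float32 and deterministic given the init
seed.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


def he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# ---------------------------------------------------------------------------
# primitive ops (forward returns output + cache; backward returns grads)
# ---------------------------------------------------------------------------


def relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_back(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


def pointwise(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Dense map applied independently at every pixel: (..., Cin) -> (..., Cout)."""
    out = x @ w + b
    return out, x


def pointwise_back(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    cin, cout = w.shape
    dw = x.reshape(-1, cin).T @ dout.reshape(-1, cout)
    db = dout.reshape(-1, cout).sum(axis=0)
    dx = dout @ w.T
    return dx, dw.astype(np.float32), db.astype(np.float32)


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    # mirror without repeating the edge (numpy 'reflect')
    idx = np.abs(idx)
    idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
    return idx


def conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 'same' convolution with reflect padding on (B, H, W, C) input.

    ``w`` has shape (9*Cin, Cout) in (dr, dc, cin) kernel order.
    """
    bsz, h, wd, cin = x.shape
    ir = _reflect_indices(h, 1)
    ic = _reflect_indices(wd, 1)
    xp = x[:, ir][:, :, ic]  # (B, H+2, W+2, C)
    cols = np.empty((bsz, h, wd, 9, cin), dtype=x.dtype)
    k = 0
    for dr in range(3):
        for dc in range(3):
            cols[:, :, :, k, :] = xp[:, dr : dr + h, dc : dc + wd, :]
            k += 1
    cols2 = cols.reshape(bsz, h, wd, 9 * cin)
    out = cols2 @ w + b
    return out, (cols2, (h, wd, ir, ic))


def conv3x3_back(dout: np.ndarray, cache, w: np.ndarray):
    cols2, (h, wd, ir, ic) = cache
    bsz = dout.shape[0]
    kin, cout = w.shape
    cin = kin // 9
    dw = cols2.reshape(-1, kin).T @ dout.reshape(-1, cout)
    db = dout.reshape(-1, cout).sum(axis=0)
    dcols = (dout @ w.T).reshape(bsz, h, wd, 9, cin)
    dxp = np.zeros((bsz, h + 2, wd + 2, cin), dtype=dout.dtype)
    k = 0
    for dr in range(3):
        for dc in range(3):
            dxp[:, dr : dr + h, dc : dc + wd, :] += dcols[:, :, :, k, :]
            k += 1
    # adjoint of reflect-pad gather: scatter-add padded grads to sources
    tmp = np.zeros((bsz, h, wd + 2, cin), dtype=dout.dtype)
    m = np.moveaxis(dxp, 1, 0)  # (H+2, B, W+2, C)
    t = np.moveaxis(tmp, 1, 0)
    np.add.at(t, ir, m)
    dx = np.zeros((bsz, h, wd, cin), dtype=dout.dtype)
    m2 = np.moveaxis(tmp, 2, 0)  # (W+2, B, H, C)
    t2 = np.moveaxis(dx, 2, 0)
    np.add.at(t2, ic, m2)
    return dx, dw.astype(np.float32), db.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, weights=None):
    """Mean (optionally class-weighted) cross-entropy + dlogits."""
    n = len(labels)
    p = np.clip(probs[np.arange(n), labels], 1e-12, None)
    if weights is None:
        loss = float(-np.log(p).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
    else:
        wv = weights[labels]
        loss = float(-(wv * np.log(p)).sum() / wv.sum())
        dlogits = probs * wv[:, None]
        dlogits[np.arange(n), labels] -= wv
        dlogits /= wv.sum()
    return loss, dlogits.astype(np.float32)


class Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
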