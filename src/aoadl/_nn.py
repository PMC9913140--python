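"""Minimal dense/convolutional building blocks in numpy.

Forward and backward passes for stride-1 "same" convolutions, ReLU, 2x2
max pooling, global average pooling and a softmax cross-entropy head.
Convolutions are computed as a sum of shifted tensordot products over the
kernel offsets, which is exact and fast enough at desk scale (small kernels,
32x32 inputs).  Everything operates on ``(N, C, H, W)`` activations.
"""

from __future__ import annotations

import numpy as np

from .errors import StructuralError


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 same-padding convolution.

    x: (N, C, H, W); w: (O, C, kh, kw) with odd kh, kw; b: (O,) or None.
    """
    n, c, h, wid = x.shape
    o, cin, kh, kw = w.shape
    if cin != c:
        raise StructuralError(f"conv input has {c} channels, kernel expects {cin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((n, o, h, wid), dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + h, j : j + wid]
            # (N,C,H,W) x (O,C) -> (N,O,H,W)
            out += np.einsum("nchw,oc->nohw", patch, w[:, :, i, j], optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


def conv2d_backward(x, w, grad_out):
    """Gradients of conv2d wrt input, weights and bias."""
    n, c, h, wid = x.shape
    o, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + h, j : j + wid]
            gw[:, :, i, j] = np.einsum("nohw,nchw->oc", grad_out, patch, optimize=True)
            gxp[:, :, i : i + h, j : j + wid] += np.einsum(
                "nohw,oc->nchw", grad_out, w[:, :, i, j], optimize=True
            )
    gx = gxp[:, :, ph : ph + h, pw : pw + wid]
    gb = grad_out.sum(axis=(0, 2, 3))
    return gx, gw, gb


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(x, grad_out):
    return grad_out * (x > 0)


def maxpool2(x):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    return xt.max(axis=(3, 5))


def maxpool2_backward(x, grad_out):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    pooled = xt.max(axis=(3, 5), keepdims=True)
    mask = xt == pooled
    # split ties evenly so the gradient check stays exact
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    gx = np.zeros_like(x)
    gx[:, :, : 2 * h2, : 2 * w2] = (mask * grad_out[:, :, :, None, :, None]).reshape(
        n, c, 2 * h2, 2 * w2
    )
    return gx


def global_avg_pool(x):
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(x, grad_out):
    n, c, h, w = x.shape
    return np.broadcast_to(grad_out[:, :, None, None], x.shape) / (h * w)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits, labels):
    """Mean cross-entropy and gradient wrt logits for integer labels."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def he_uniform(shape, fan_in, rng):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)
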