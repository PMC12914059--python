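"""Minimal numpy residual conv-net: layers, forward/backward, Adam.

Kept deliberately small — 3x3 convolutions, three residual stages
(16/32/64 channels with stride-2 downsampling between), global average
pooling and a linear softmax head — so that it trains in seconds to
minutes on one CPU for the synthetic datasets this package generates.
"""

from __future__ import annotations

import numpy as np


def conv3x3_forward(x, w, b, stride=1):
    """x: (N,C,H,W), w: (F,C,3,3), zero padding 1. Returns (out, cache)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    oh = (h + 2 - 3) // stride + 1
    ow = (wd + 2 - 3) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, f, oh, ow), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            xs = xp[:, :, di:di + stride * oh:stride, dj:dj + stride * ow:stride]
            out += np.einsum("fc,nchw->nfhw", w[:, :, di, dj], xs, optimize=True)
    out += b[None, :, None, None]
    return out, (x, w, stride, oh, ow)


def conv3x3_backward(dout, cache):
    x, w, stride, oh, ow = cache
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(3):
        for dj in range(3):
            xs = xp[:, :, di:di + stride * oh:stride, dj:dj + stride * ow:stride]
            dw[:, :, di, dj] = np.einsum("nfhw,nchw->fc", dout, xs, optimize=True)
            dxp[:, :, di:di + stride * oh:stride, dj:dj + stride * ow:stride] += \
                np.einsum("fc,nfhw->nchw", w[:, :, di, dj], dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dw, db


def conv1x1_stride2_forward(x, w):
    """Projection shortcut: subsample by 2 then 1x1 conv. w: (F,C)."""
    xs = x[:, :, ::2, ::2]
    out = np.einsum("fc,nchw->nfhw", w, xs, optimize=True)
    return out, (xs, w, x.shape)


def conv1x1_stride2_backward(dout, cache):
    xs, w, xshape = cache
    dw = np.einsum("nfhw,nchw->fc", dout, xs, optimize=True)
    dxs = np.einsum("fc,nfhw->nchw", w, dout, optimize=True)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, ::2, ::2] = dxs
    return dx, dw


def he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class ResNet:
    """Stem conv + 3 residual blocks (16/32/64) + GAP + linear head."""

    def __init__(self, in_channels, n_classes, widths=(16, 32, 64), seed=0):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = widths
        p = {}
        p["stem_w"] = he_init(rng, (w1, in_channels, 3, 3), in_channels * 9)
        p["stem_b"] = np.zeros(w1)
        # block1: w1 -> w1, stride 1, identity shortcut
        p["b1c1_w"] = he_init(rng, (w1, w1, 3, 3), w1 * 9)
        p["b1c1_b"] = np.zeros(w1)
        p["b1c2_w"] = he_init(rng, (w1, w1, 3, 3), w1 * 9)
        p["b1c2_b"] = np.zeros(w1)
        # block2: w1 -> w2, stride 2, projection shortcut
        p["b2c1_w"] = he_init(rng, (w2, w1, 3, 3), w1 * 9)
        p["b2c1_b"] = np.zeros(w2)
        p["b2c2_w"] = he_init(rng, (w2, w2, 3, 3), w2 * 9)
        p["b2c2_b"] = np.zeros(w2)
        p["b2p_w"] = he_init(rng, (w2, w1), w1)
        # block3: w2 -> w3, stride 2, projection shortcut
        p["b3c1_w"] = he_init(rng, (w3, w2, 3, 3), w2 * 9)
        p["b3c1_b"] = np.zeros(w3)
        p["b3c2_w"] = he_init(rng, (w3, w3, 3, 3), w3 * 9)
        p["b3c2_b"] = np.zeros(w3)
        p["b3p_w"] = he_init(rng, (w3, w2), w2)
        p["head_w"] = rng.normal(0.0, np.sqrt(1.0 / w3), size=(w3, n_classes))
        p["head_b"] = np.zeros(n_classes)
        self.params = p

    def forward(self, x, want_cache=False):
        p = self.params
        cache = {}
        h0, cache["stem"] = conv3x3_forward(x, p["stem_w"], p["stem_b"])
        a0 = np.maximum(h0, 0)
        cache["a0"] = a0 > 0

        # block 1 (identity)
        h1, cache["b1c1"] = conv3x3_forward(a0, p["b1c1_w"], p["b1c1_b"])
        a1 = np.maximum(h1, 0)
        cache["a1"] = a1 > 0
        h2, cache["b1c2"] = conv3x3_forward(a1, p["b1c2_w"], p["b1c2_b"])
        r1 = np.maximum(a0 + h2, 0)
        cache["r1"] = r1 > 0

        # block 2 (stride 2, projection)
        h3, cache["b2c1"] = conv3x3_forward(r1, p["b2c1_w"], p["b2c1_b"], stride=2)
        a3 = np.maximum(h3, 0)
        cache["a3"] = a3 > 0
        h4, cache["b2c2"] = conv3x3_forward(a3, p["b2c2_w"], p["b2c2_b"])
        sc2, cache["b2p"] = conv1x1_stride2_forward(r1, p["b2p_w"])
        r2 = np.maximum(sc2 + h4, 0)
        cache["r2"] = r2 > 0

        # block 3 (stride 2, projection)
        h5, cache["b3c1"] = conv3x3_forward(r2, p["b3c1_w"], p["b3c1_b"], stride=2)
        a5 = np.maximum(h5, 0)
        cache["a5"] = a5 > 0
        h6, cache["b3c2"] = conv3x3_forward(a5, p["b3c2_w"], p["b3c2_b"])
        sc3, cache["b3p"] = conv1x1_stride2_forward(r2, p["b3p_w"])
        r3 = np.maximum(sc3 + h6, 0)
        cache["r3"] = r3 > 0

        pooled = r3.mean(axis=(2, 3))  # (N, w3)
        cache["pooled_in_shape"] = r3.shape
        cache["pooled"] = pooled
        logits = pooled @ p["head_w"] + p["head_b"]
        if want_cache:
            return logits, cache
        return logits

    def backward(self, dlogits, cache):
        p = self.params
        g = {}
        pooled = cache["pooled"]
        g["head_w"] = pooled.T @ dlogits
        g["head_b"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["head_w"].T
        n, c, h, w = cache["pooled_in_shape"]
        dr3 = np.broadcast_to(dpooled[:, :, None, None] / (h * w), (n, c, h, w)).copy()
        dr3 *= cache["r3"]

        dx, g["b3c2_w"], g["b3c2_b"] = conv3x3_backward(dr3, cache["b3c2"])
        dx *= cache["a5"]
        dr2a, g["b3c1_w"], g["b3c1_b"] = conv3x3_backward(dx, cache["b3c1"])
        dr2b, g["b3p_w"] = conv1x1_stride2_backward(dr3, cache["b3p"])
        dr2 = (dr2a + dr2b) * cache["r2"]

        dx, g["b2c2_w"], g["b2c2_b"] = conv3x3_backward(dr2, cache["b2c2"])
        dx *= cache["a3"]
        dr1a, g["b2c1_w"], g["b2c1_b"] = conv3x3_backward(dx, cache["b2c1"])
        dr1b, g["b2p_w"] = conv1x1_stride2_backward(dr2, cache["b2p"])
        dr1 = (dr1a + dr1b) * cache["r1"]

        dx, g["b1c2_w"], g["b1c2_b"] = conv3x3_backward(dr1, cache["b1c2"])
        dx *= cache["a1"]
        da0a, g["b1c1_w"], g["b1c1_b"] = conv3x3_backward(dx, cache["b1c1"])
        da0 = (da0a + dr1) * cache["a0"]

        _, g["stem_w"], g["stem_b"] = conv3x3_backward(da0, cache["stem"])
        return g


def softmax_cross_entropy(logits, y_idx):
    """Mean cross-entropy and gradient wrt logits. y_idx: int class indices."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), y_idx] + 1e-12))
    dlogits = probs.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
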