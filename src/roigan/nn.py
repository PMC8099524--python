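"""Minimal NumPy neural-network primitives with explicit backward passes.

Everything operates on single samples shaped ``(C, H, W)`` (batch size 1 is
the training convention; instance normalization makes per-sample statistics
the only ones ever needed).  Each ``*_forward`` returns ``(output, cache)``
and the matching ``*_backward`` consumes the cache and returns input and
parameter gradients.  All operations are deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

DTYPE = np.float32


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Patch matrix of ``x`` (C,H,W) -> (Ho*Wo, C*k*k). View-based, then copied
    by reshape, so the result is safe to keep in a cache."""
    c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sc, sh, sw = x.strides
    windows = as_strided(
        x,
        shape=(c, ho, wo, k, k),
        strides=(sc, sh * stride, sw * stride, sh, sw),
    )
    # (ho, wo, c, k, k) -> rows ordered like the output raster
    return np.ascontiguousarray(windows.transpose(1, 2, 0, 3, 4)).reshape(ho * wo, c * k * k)


def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad)))


def conv2d_forward(x, w, b, stride=1, pad=0):
    """x (Ci,H,W), w (Co,Ci,k,k), b (Co,) -> y (Co,Ho,Wo)."""
    co, ci, k, _ = w.shape
    xp = _pad2d(x, pad)
    cols = _im2col(xp, k, stride)
    y = cols @ w.reshape(co, -1).T + b
    ho = (xp.shape[1] - k) // stride + 1
    wo = (xp.shape[2] - k) // stride + 1
    y = y.T.reshape(co, ho, wo)
    cache = (cols, x.shape)
    return y, cache


def _dilate(g: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return g
    c, h, w = g.shape
    out = np.zeros((c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=g.dtype)
    out[:, ::stride, ::stride] = g
    return out


def conv2d_backward(gy, cache, w, stride=1, pad=0):
    """Gradients of conv2d_forward. Returns (gx, gw, gb)."""
    cols, x_shape = cache
    co, ci, k, _ = w.shape
    gy_mat = gy.reshape(co, -1)            # (Co, P)
    gb = gy_mat.sum(axis=1)
    gw = (gy_mat @ cols).reshape(w.shape)
    # data gradient: dilate gy, full-pad, correlate with flipped transposed
    # kernel, then slice away the zero padding of the forward pass
    gyd = _dilate(gy, stride)
    wt = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Ci, Co, k, k)
    gx_pad, _ = conv2d_forward(
        _pad2d(gyd, k - 1), wt, np.zeros(ci, dtype=gy.dtype), stride=1, pad=0
    )
    # floor in the forward shape arithmetic may leave gx_pad short; zero-extend
    _, h, wdt = x_shape
    gx = np.zeros(x_shape, dtype=gy.dtype)
    gh = min(h, gx_pad.shape[1] - pad)
    gw_ = min(wdt, gx_pad.shape[2] - pad)
    gx[:, :gh, :gw_] = gx_pad[:, pad:pad + gh, pad:pad + gw_]
    return gx, gw, gb


def deconv2d_forward(x, w, b, stride=2, pad=1, output_padding=1):
    """Transposed convolution. x (Ci,H,W), w (Ci,Co,k,k) -> y (Co,Hout,Wout)
    with Hout = (H-1)*stride - 2*pad + k + output_padding."""
    ci, co, k, _ = w.shape
    xd = _dilate(x, stride)
    m = k - 1 - pad
    if m < 0:
        raise ValueError("pad larger than kernel-1 is not supported")
    xdp = np.pad(xd, ((0, 0), (m, m + output_padding), (m, m + output_padding)))
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Co, Ci, k, k)
    y, (cols, _) = conv2d_forward(xdp, wf, b, stride=1, pad=0)
    cache = (cols, x.shape, xdp.shape)
    return y, cache


def deconv2d_backward(gy, cache, w, stride=2, pad=1, output_padding=1):
    cols, x_shape, xdp_shape = cache
    ci, co, k, _ = w.shape
    gy_mat = gy.reshape(co, -1)
    gb = gy_mat.sum(axis=1)
    gwf = (gy_mat @ cols).reshape(co, ci, k, k)
    gw = gwf.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1].copy()
    # gradient w.r.t. the dilated+padded input: the forward used flip(w)^T, whose
    # adjoint kernel is w itself viewed as a (Ci out, Co in) convolution
    g_xdp, _ = conv2d_forward(
        _pad2d(gy, k - 1), w, np.zeros(ci, dtype=gy.dtype), stride=1, pad=0
    )
    m = k - 1 - pad
    h_dil = (x_shape[1] - 1) * stride + 1
    w_dil = (x_shape[2] - 1) * stride + 1
    g_xd = g_xdp[:, m:m + h_dil, m:m + w_dil]
    gx = g_xd[:, ::stride, ::stride].copy()
    return gx, gw, gb


# ---------------------------------------------------------------------------
# normalization / padding / pointwise


def instance_norm_forward(x, eps=1e-5):
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat, (xhat, inv)


def instance_norm_backward(gy, cache):
    xhat, inv = cache
    m1 = gy.mean(axis=(1, 2), keepdims=True)
    m2 = (gy * xhat).mean(axis=(1, 2), keepdims=True)
    return inv * (gy - m1 - xhat * m2)


def mirror_pad_forward(x, pad):
    y = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")
    return y, (x.shape, pad)


def mirror_pad_backward(gy, cache):
    x_shape, pad = cache
    _, h, w = x_shape
    idx = np.pad(
        np.arange(h * w).reshape(h, w), ((pad, pad), (pad, pad)), mode="reflect"
    ).ravel()
    gx = np.empty(x_shape, dtype=gy.dtype)
    for c in range(x_shape[0]):
        gx[c] = np.bincount(idx, weights=gy[c].ravel(), minlength=h * w).reshape(h, w)
    return gx.astype(gy.dtype, copy=False)


def activation_forward(x, name, slope=0.2):
    if name == "relu":
        y = np.maximum(x, 0)
        return y, (name, x > 0)
    if name == "leaky_relu":
        y = np.where(x > 0, x, slope * x)
        return y, (name, x > 0, slope)
    if name == "sigmoid":
        # numerically stable two-branch form (no overflow for large |x|)
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        return y, (name, y)
    if name == "tanh":
        y = np.tanh(x)
        return y, (name, y)
    raise ValueError(f"unknown activation {name!r}")


def activation_backward(gy, cache):
    name = cache[0]
    if name == "relu":
        return gy * cache[1]
    if name == "leaky_relu":
        _, pos, slope = cache
        return gy * np.where(pos, 1.0, slope)
    if name == "sigmoid":
        y = cache[1]
        return gy * y * (1 - y)
    if name == "tanh":
        y = cache[1]
        return gy * (1 - y * y)
    raise ValueError(name)


def dense_forward(x, w, b):
    """x flat (n,), w (out,n), b (out,) -> (out,)."""
    return w @ x + b, x


def dense_backward(gy, cache, w):
    x = cache
    gw = np.outer(gy, x)
    gb = gy.copy()
    gx = w.T @ gy
    return gx, gw, gb


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over a dict of parameter arrays (updated in place)."""

    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state(self):
        return {"t": self.t, "m": self.m, "v": self.v}
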