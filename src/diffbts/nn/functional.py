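"""Functional neural-network primitives on NumPy arrays.

All operations are written with :mod:`autograd.numpy` so that any scalar
loss composed from them can be differentiated with ``autograd.grad``.
Parameters are plain ``numpy`` arrays held in nested dicts/lists
("pytrees"); there is no mutable layer state.

Convolutions are expressed as shifted-slice gathers followed by a single
batched matmul, which keeps both the forward and the autograd-derived
backward pass inside BLAS.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive


def _sigmoid_raw(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)  # stable for large |x|


@primitive
def sigmoid(x):
    """Numerically stable logistic function (fused autograd primitive)."""
    return _sigmoid_raw(x)


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


@primitive
def silu(x):
    """SiLU / swish activation, ``x * sigmoid(x)`` (fused primitive)."""
    return x * _sigmoid_raw(x)


def _silu_vjp(ans, x):
    def vjp(g):
        s = _sigmoid_raw(x)
        return g * (s * (1.0 + x * (1.0 - s)))

    return vjp


defvjp(silu, _silu_vjp)


@primitive
def softmax(x, axis):
    """Softmax along ``axis`` with the usual max-shift for stability."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _softmax_vjp(ans, x, axis):
    return lambda g: ans * (g - np.sum(ans * g, axis=axis, keepdims=True))


defvjp(softmax, _softmax_vjp)


def linear(x, w, b):
    """Affine map ``x @ w + b`` over the last axis."""
    return anp.matmul(x, w) + b


def _im2col(x, kshape):
    """Zero-padded 'same' patch matrix (B, C*kd*kh*kw, D*H*W); one copy.

    The gather runs as one large W-contiguous slice copy per kernel
    offset, which is substantially faster than a transposed window view.
    """
    kd, kh, kw = kshape
    b, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kd // 2,) * 2, (kh // 2,) * 2, (kw // 2,) * 2))
    cols = np.empty((b, c, kd * kh * kw, d, h, w), dtype=x.dtype)
    m = 0
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                cols[:, :, m] = xp[:, :, i : i + d, j : j + h, k : k + w]
                m += 1
    return cols.reshape(b, c * kd * kh * kw, d * h * w)


@primitive
def _conv3d_core(x, w):
    """Correlation with 'same' zero padding: one im2col + one BLAS GEMM.

    A hand-written autograd primitive: the input gradient is again a
    correlation (with the spatially flipped, channel-transposed kernel),
    so the whole backward pass stays in gather + GEMM form with no
    scatter-add.
    """
    cout, cin, kd, kh, kw = w.shape
    b, c, d, h, wd = x.shape
    cols = _im2col(x, (kd, kh, kw))  # (B, C_in*k^3, n)
    y = np.matmul(w.reshape(cout, cin * kd * kh * kw), cols)
    return y.reshape(b, cout, d, h, wd)


def _conv3d_vjp_x(ans, x, w):
    wf = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    return lambda g: _conv3d_core(g, wf)


def _conv3d_vjp_w(ans, x, w):
    def vjp(g):
        cout, cin, kd, kh, kw = w.shape
        b, c, d, h, wd = x.shape
        cols = _im2col(x, (kd, kh, kw))
        gm = g.reshape(b, cout, d * h * wd)
        # sum over batch of g @ cols^T; BLAS consumes the stride-transpose
        return np.matmul(gm, cols.swapaxes(1, 2)).sum(axis=0).reshape(w.shape)

    return vjp


defvjp(_conv3d_core, _conv3d_vjp_x, _conv3d_vjp_w)


def conv3d(x, w, b):
    """3D convolution (correlation) with 'same' zero padding.

    Parameters
    ----------
    x : (B, C_in, D, H, W) array
    w : (C_out, C_in, k, k, k) array, k odd
    b : (C_out,) array
    """
    if x.shape[1] != w.shape[1]:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, kernel expects {w.shape[1]}")
    return _conv3d_core(x, w) + anp.reshape(b, (1, w.shape[0], 1, 1, 1))


def conv_transpose3d_2x(x, w, b):
    """Transposed convolution with kernel 2 and stride 2 (exact 2x upsampling).

    Parameters
    ----------
    x : (B, C_in, D, H, W) array
    w : (C_in, C_out, 2, 2, 2) array
    b : (C_out,) array
    """
    cin, cout = w.shape[:2]
    bsz, cin2, d, h, wd = x.shape
    if cin2 != cin:
        raise ValueError(f"conv_transpose3d_2x: channel mismatch {cin2} != {cin}")
    wmat = anp.reshape(w, (cin, cout * 8))
    y = anp.matmul(anp.swapaxes(anp.reshape(x, (bsz, cin, d * h * wd)), 1, 2), wmat)
    y = anp.reshape(y, (bsz, d, h, wd, cout, 2, 2, 2))
    y = anp.transpose(y, (0, 4, 1, 5, 2, 6, 3, 7))
    y = anp.reshape(y, (bsz, cout, 2 * d, 2 * h, 2 * wd))
    return y + anp.reshape(b, (1, cout, 1, 1, 1))


def max_pool3d_2x(x):
    """2x2x2 max pooling; spatial sizes must be even."""
    bsz, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"max_pool3d_2x: odd spatial size {(d, h, w)}")
    x = anp.reshape(x, (bsz, c, d // 2, 2, h // 2, 2, w // 2, 2))
    x = anp.max(x, axis=7)
    x = anp.max(x, axis=5)
    x = anp.max(x, axis=3)
    return x


_GN_EPS = 1e-5
_GN_AXES = (2, 3, 4, 5)


@primitive
def _gn_normalize(xg):
    """Zero-mean unit-variance normalization over group axes (2, 3, 4, 5)."""
    mu = np.mean(xg, axis=_GN_AXES, keepdims=True)
    var = np.mean((xg - mu) ** 2, axis=_GN_AXES, keepdims=True)
    return (xg - mu) / np.sqrt(var + _GN_EPS)


def _gn_normalize_vjp(ans, xg):
    def vjp(g):
        var = np.var(xg, axis=_GN_AXES, keepdims=True)
        s = np.sqrt(var + _GN_EPS)
        gm = np.mean(g, axis=_GN_AXES, keepdims=True)
        gx = np.mean(g * ans, axis=_GN_AXES, keepdims=True)
        return (g - gm - ans * gx) / s

    return vjp


defvjp(_gn_normalize, _gn_normalize_vjp)


def group_norm(x, gamma, beta, groups, eps=_GN_EPS):
    """Group normalization over (channel-group, D, H, W).

    ``groups`` is reduced to the largest divisor of the channel count not
    exceeding it, so narrow feature maps degrade gracefully.
    """
    bsz, c, d, h, w = x.shape
    g = min(groups, c)
    while c % g:
        g -= 1
    xg = anp.reshape(x, (bsz, g, c // g, d, h, w))
    x = anp.reshape(_gn_normalize(xg), (bsz, c, d, h, w))
    return x * anp.reshape(gamma, (1, c, 1, 1, 1)) + anp.reshape(beta, (1, c, 1, 1, 1))


def time_embedding(t, dim):
    """Sinusoidal encoding of integer diffusion steps.

    Parameters
    ----------
    t : int or (B,) array of step indices
    dim : even embedding width

    Returns
    -------
    (dim,) or (B, dim) float array (constant w.r.t. parameters).
    """
    t = np.asarray(t, dtype=float)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[..., None] * freqs
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)
    return emb if t.ndim else emb.reshape(dim)
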