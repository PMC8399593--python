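"""Functional CNN primitives (forward + backward) on NCHW float arrays.

Minimal autodiff surface for the segmentation network: 2-D convolution
(same padding, stride 1 or 2), batch normalization, ReLU, 2x2 max-pooling,
4x4/stride-2 transposed convolution (exact x2 upsampling), channel
concatenation, element-wise addition and per-pixel softmax.  Each
``*_forward`` returns ``(output, cache)``; the matching ``*_backward``
consumes the cache and the upstream gradient.

Convolutions are evaluated as an im2col matrix product; the backward data
pass scatters the column gradient back with one vectorized slice-add per
kernel tap.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_begin, pad_end) for TensorFlow-style 'same' padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    beg = total // 2
    return out, beg, total - beg


def conv2d_forward(x, w, b, stride=1):
    """x: (N,C,H,W); w: (F,C,kh,kw); b: (F,). Same padding."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    oh, pt, pb = _same_pad(h, kh, stride)
    ow, pl, pr = _same_pad(wd, kw, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win[:, :, :oh, :ow]  # (N,C,oh,ow,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    y = cols @ w.reshape(f, -1).T + b
    y = y.reshape(n, oh, ow, f).transpose(0, 3, 1, 2)
    cache = (cols, x.shape, w, stride, (pt, pl), (oh, ow))
    return np.ascontiguousarray(y), cache


def conv2d_backward(dy, cache):
    cols, x_shape, w, stride, (pt, pl), (oh, ow) = cache
    n, c, h, wd = x_shape
    f, _, kh, kw = w.shape
    dy2 = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
    dw = (dy2.T @ cols).reshape(w.shape)
    db = dy2.sum(axis=0)
    dcols = (dy2 @ w.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
    hp = h + pt + max((oh - 1) * stride + kh - h - pt, 0)
    wp = wd + pl + max((ow - 1) * stride + kw - wd - pl, 0)
    hp = max(hp, (oh - 1) * stride + kh)
    wp = max(wp, (ow - 1) * stride + kw)
    dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    dx = dxp[:, :, pt : pt + h, pl : pl + wd]
    return np.ascontiguousarray(dx), dw, db


def conv_transpose2d_forward(x, w, b):
    """Exact x2 upsampling: kernel 4x4, stride 2, symmetric crop of 1.

    x: (N,C,H,W); w: (C,F,4,4); b: (F,). Output (N,F,2H,2W) with
    y[2h+i-1, 2w+j-1] += x[h,w] * w[i,j] (out-of-range taps dropped).
    """
    n, c, h, wd = x.shape
    _, f, kh, kw = w.shape
    oh, ow = 2 * h, 2 * wd
    x2 = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * wd, c)
    # One GEMM for all taps, then scatter each tap's contribution.
    taps = (x2 @ w.reshape(c, f * kh * kw)).reshape(n, h, wd, f, kh, kw)
    ypad = np.zeros((n, f, oh + 2, ow + 2), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ypad[:, :, i : i + oh : 2, j : j + ow : 2] += taps[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    y = ypad[:, :, 1 : 1 + oh, 1 : 1 + ow] + b[None, :, None, None]
    return np.ascontiguousarray(y), (x2, x.shape, w)


def conv_transpose2d_backward(dy, cache):
    x2, x_shape, w = cache
    n, c, h, wd = x_shape
    _, f, kh, kw = w.shape
    oh, ow = 2 * h, 2 * wd
    dypad = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # Gather every tap's upstream gradient, then one GEMM each for dx, dw.
    dtaps = np.empty((n, h, wd, f, kh, kw), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dtaps[:, :, :, :, i, j] = dypad[
                :, :, i : i + oh : 2, j : j + ow : 2
            ].transpose(0, 2, 3, 1)
    dtaps2 = dtaps.reshape(n * h * wd, f * kh * kw)
    dx = (dtaps2 @ w.reshape(c, -1).T).reshape(n, h, wd, c).transpose(0, 3, 1, 2)
    dw = (x2.T @ dtaps2).reshape(w.shape)
    db = dy.sum(axis=(0, 2, 3))
    return np.ascontiguousarray(dx), dw, db


def batchnorm_forward(x, gamma, beta, running_mean, running_var, training):
    """Per-channel batch normalization with affine transform.

    In training mode the batch statistics are used and the running
    estimates updated in place; in inference mode the running estimates
    normalize the input.
    """
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - BN_MOMENTUM
        running_mean += BN_MOMENTUM * mean
        running_var *= 1.0 - BN_MOMENTUM
        running_var += BN_MOMENTUM * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, inv_std, gamma, training)


def batchnorm_backward(dy, cache):
    xhat, inv_std, gamma, training = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    if not training:
        dx = dy * (gamma * inv_std)[None, :, None, None]
        return dx, dgamma, dbeta
    dxhat = dy * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
    ) * inv_std[None, :, None, None]
    return dx, dgamma, dbeta


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(dy, cache):
    return dy * cache


def maxpool2x2_forward(x):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    return y, (xr, y)


def maxpool2x2_backward(dy, cache):
    xr, y = cache
    mask = xr == y[:, :, :, None, :, None]
    dxr = mask * dy[:, :, :, None, :, None]
    n, c, h2, _, w2, _ = xr.shape
    return dxr.reshape(n, c, h2 * 2, w2 * 2)


def concat_forward(a, b):
    if a.shape[2:] != b.shape[2:]:
        raise ValueError("depth concatenation requires equal spatial sizes")
    return np.concatenate([a, b], axis=1), (a.shape[1],)


def concat_backward(dy, cache):
    (c_a,) = cache
    return dy[:, :c_a], dy[:, c_a:]


def add_forward(a, b):
    if a.shape != b.shape:
        raise ValueError(
            f"addition requires identical shapes, got {a.shape} vs {b.shape}"
        )
    return a + b, None


def softmax_forward(x):
    """Per-pixel softmax over the channel axis."""
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p, p


def weighted_ce_logit_grad(probs, truth, class_weights=(1.0, 1.0)):
    """Gradient of the mean weighted cross-entropy w.r.t. the logits.

    probs: (N,2,H,W) softmax output; truth: (N,H,W) int in {0, 1}.
    Softmax and loss are fused: d(loss)/d(logit_c) = w_t (p_c - [c == t]) / M.
    """
    n, k, h, w = probs.shape
    m = n * h * w
    onehot = np.zeros_like(probs)
    idx = np.indices(truth.shape)
    onehot[idx[0], truth, idx[1], idx[2]] = 1.0
    wmap = np.where(truth == 1, class_weights[1], class_weights[0])
    return ((probs - onehot) * wmap[:, None, :, :] / m).astype(probs.dtype)
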