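"""Differentiable operations for the segmentation stack.

Convolutions are computed by unrolling kernel taps into a column buffer
(im2col) and dispatching a single matrix product per layer to BLAS; the
transposed convolution is the exact adjoint (column scatter).  Every op
returns a :class:`~cuffseg.nn.autograd.Tensor` and registers a backward
closure when gradients are enabled.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .autograd import Tensor, as_tensor, make_result

__all__ = [
    "add", "mul", "reshape", "concat", "relu", "sigmoid", "matmul",
    "conv2d", "conv_transpose2d", "batch_norm2d", "max_pool2d",
    "global_avg_pool", "bce_loss",
]


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_sum_to_shape(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_sum_to_shape(g, b.data.shape))

    return make_result(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_sum_to_shape(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_sum_to_shape(g * a.data, b.data.shape))

    return make_result(out, (a, b), backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    old = x.data.shape
    out = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g.reshape(old))

    return make_result(out, (x,), backward)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(idx)])

    return make_result(out, ts, backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    out = np.maximum(x.data, 0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * (x.data > 0))

    return make_result(out, (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * out * (1.0 - out))

    return make_result(out, (x,), backward)


def matmul(a, b) -> Tensor:
    """2-D matrix product (used by the squeeze-excitation MLP)."""
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g @ b.data.T)
        if b.requires_grad:
            b.accumulate_grad(a.data.T @ g)

    return make_result(out, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, stride: int, padding: int, dilation: int) -> int:
    return (n + 2 * padding - dilation * (k - 1) - 1) // stride + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        hi = i * dilation
        hs = slice(hi, hi + (oh - 1) * stride + 1, stride)
        for j in range(kw):
            wj = j * dilation
            ws = slice(wj, wj + (ow - 1) * stride + 1, stride)
            cols[:, :, i, j] = xp[:, :, hs, ws]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, xp_shape: tuple, kh: int, kw: int,
            stride: int, dilation: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i * dilation
        hs = slice(hi, hi + (oh - 1) * stride + 1, stride)
        for j in range(kw):
            wj = j * dilation
            ws = slice(wj, wj + (ow - 1) * stride + 1, stride)
            dxp[:, :, hs, ws] += dcols[:, :, i, j]
    return dxp


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D cross-correlation, channels-first; weight (OC, C, KH, KW)."""
    x, w = as_tensor(x), as_tensor(w)
    bias = as_tensor(b) if b is not None else None
    n, c, h, wd = x.data.shape
    oc, _, kh, kw = w.data.shape
    oh = _out_size(h, kh, stride, padding, dilation)
    ow = _out_size(wd, kw, stride, padding, dilation)
    if oh < 1 or ow < 1:
        raise ValueError("convolution output would be empty")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)
    wmat = w.data.reshape(oc, -1)
    y = np.matmul(wmat, cols)                      # (N, OC, OH*OW)
    if bias is not None:
        y += bias.data.reshape(1, oc, 1)
    out = y.reshape(n, oc, oh, ow)
    xp_shape = xp.shape

    def backward(g):
        g2 = g.reshape(n, oc, oh * ow)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w.accumulate_grad(dw.reshape(w.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, g2)
            dxp = _col2im(dcols, xp_shape, kh, kw, stride, dilation, oh, ow)
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wd]
            x.accumulate_grad(dxp)

    parents = (x, w) if bias is None else (x, w, bias)
    return make_result(out, parents, backward)


def conv_transpose2d(x, w, b=None, stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed 2-D convolution; weight (C_in, OC, KH, KW).

    The forward pass is the adjoint of :func:`conv2d`: each input pixel
    scatters a weighted kernel into the (strided) output grid.
    """
    x, w = as_tensor(x), as_tensor(w)
    bias = as_tensor(b) if b is not None else None
    n, c, h, wd = x.data.shape
    _, oc, kh, kw = w.data.shape
    oh = (h - 1) * stride - 2 * padding + kh + output_padding
    ow = (wd - 1) * stride - 2 * padding + kw + output_padding
    wmat = w.data.reshape(c, -1)                   # (C, OC*KH*KW)
    xf = x.data.reshape(n, c, h * wd)
    cols = np.matmul(wmat.T, xf)                   # (N, OC*KH*KW, H*W)
    cols6 = cols.reshape(n, oc, kh, kw, h, wd)
    out_p = np.zeros((n, oc, oh + 2 * padding, ow + 2 * padding), dtype=x.data.dtype)
    for i in range(kh):
        hs = slice(i, i + (h - 1) * stride + 1, stride)
        for j in range(kw):
            ws = slice(j, j + (wd - 1) * stride + 1, stride)
            out_p[:, :, hs, ws] += cols6[:, :, i, j]
    out = out_p[:, :, padding:padding + oh, padding:padding + ow]
    if bias is not None:
        out = out + bias.data.reshape(1, oc, 1, 1)
    else:
        out = np.ascontiguousarray(out)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        dcols = np.empty((n, oc, kh, kw, h, wd), dtype=g.dtype)
        for i in range(kh):
            hs = slice(i, i + (h - 1) * stride + 1, stride)
            for j in range(kw):
                ws = slice(j, j + (wd - 1) * stride + 1, stride)
                dcols[:, :, i, j] = gp[:, :, hs, ws]
        dcols2 = dcols.reshape(n, oc * kh * kw, h * wd)
        if x.requires_grad:
            dx = np.matmul(wmat, dcols2)
            x.accumulate_grad(dx.reshape(x.data.shape))
        if w.requires_grad:
            dw = np.matmul(xf, dcols2.transpose(0, 2, 1)).sum(axis=0)
            w.accumulate_grad(dw.reshape(w.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if bias is None else (x, w, bias)
    return make_result(out, parents, backward)


# ---------------------------------------------------------------------------
# normalisation / pooling
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation with running-statistics tracking.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training (exponential moving average, unbiased variance) and used verbatim
    in eval mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, wd = x.data.shape
    m = n * h * wd
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        unbias = var * m / max(m - 1, 1)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * unbias
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gw = gamma.data.reshape(1, c, 1, 1)
            if training:
                gsum = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                gx_sum = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                dx = (gw * inv_std.reshape(1, c, 1, 1) / m) * (
                    m * g - gsum - xhat * gx_sum)
            else:
                dx = gw * inv_std.reshape(1, c, 1, 1) * g
            x.accumulate_grad(dx)

    return make_result(out, (x, gamma, beta), backward)


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    n, c, h, wd = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (wd + 2 * padding - kernel) // stride + 1
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    windows = np.empty((n, c, kernel * kernel, oh, ow), dtype=x.data.dtype)
    for i in range(kernel):
        hs = slice(i, i + (oh - 1) * stride + 1, stride)
        for j in range(kernel):
            ws = slice(j, j + (ow - 1) * stride + 1, stride)
            windows[:, :, i * kernel + j] = xp[:, :, hs, ws]
    arg = windows.argmax(axis=2)
    out = np.take_along_axis(windows, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=g.dtype)
        for i in range(kernel):
            hs = slice(i, i + (oh - 1) * stride + 1, stride)
            for j in range(kernel):
                ws = slice(j, j + (ow - 1) * stride + 1, stride)
                k = i * kernel + j
                dxp[:, :, hs, ws] += g * (arg == k)
        x.accumulate_grad(dxp[:, :, padding:padding + h, padding:padding + wd])

    return make_result(out, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """Spatial mean, (N, C, H, W) -> (N, C) — the squeeze step."""
    x = as_tensor(x)
    n, c, h, wd = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(
                g[:, :, None, None] / (h * wd), x.data.shape).astype(g.dtype))

    return make_result(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(pred, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy on probabilities.

    Predictions are clamped to [eps, 1-eps] before the logarithms so the
    loss stays finite for saturated outputs.
    """
    pred = as_tensor(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred.data.shape != t.shape:
        raise ValueError(
            f"prediction shape {pred.data.shape} != target shape {t.shape}")
    t = t.astype(pred.data.dtype)
    p = np.clip(pred.data, eps, 1.0 - eps)
    n = p.size
    out = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()

    def backward(g):
        if pred.requires_grad:
            inside = (pred.data > eps) & (pred.data < 1.0 - eps)
            dp = (p - t) / (p * (1.0 - p)) / n
            pred.accumulate_grad(g * dp * inside)

    return make_result(np.asarray(out, dtype=pred.data.dtype), (pred,), backward)
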