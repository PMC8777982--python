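"""Low-level convolution arithmetic on NHWC float arrays.

Convolutions are computed by shift-and-accumulate GEMM: for each kernel
offset (i, j) a contiguous shifted copy of the (padded) input is
multiplied by the (C_in, C_out) weight slice and accumulated. This keeps
every copy memcpy-friendly and every matrix product large, which is what
a single-CPU BLAS wants; a patch-matrix (im2col) layout is never
materialized. The transposed paths (gradient w.r.t. a convolution input,
and transposed-convolution forward) share one "dilate then correlate"
helper so a single routine is exercised by the gradient checks.

Weight layout is (k, k, C_in, C_out) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_weight_grad",
    "conv2d_input_grad",
    "conv_transpose2d",
    "conv_transpose2d_input_grad",
    "conv_transpose2d_weight_grad",
    "maxpool2x2",
    "maxpool2x2_input_grad",
]


def _shift_view(xp, i, j, ho, wo, stride):
    return xp[:, i:i + stride * (ho - 1) + 1:stride,
              j:j + stride * (wo - 1) + 1:stride]


def conv2d(x, w, stride=1, pad=1, keep_ctx=False):
    """Cross-correlate ``x`` (N,H,W,Cin) with ``w`` (k,k,Cin,Cout).

    With k=3, pad=1 the output side is ceil(H/stride) for stride in {1,2}
    (the ceil-mode contract every encoder stage obeys). With ``keep_ctx``
    the shifted input copies are returned for the weight-gradient pass.
    """
    k, _, cin, cout = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
    n, hp, wp, _ = xp.shape
    ho, wo = (hp - k) // stride + 1, (wp - k) // stride + 1
    y = np.zeros((n * ho * wo, cout), dtype=x.dtype)
    ctx = [] if keep_ctx else None
    buf = None
    for i in range(k):
        for j in range(k):
            view = _shift_view(xp, i, j, ho, wo, stride)
            if keep_ctx:
                s = np.ascontiguousarray(view)
                ctx.append(s)
            else:
                if buf is None:
                    buf = np.empty((n, ho, wo, cin), dtype=x.dtype)
                np.copyto(buf, view)
                s = buf
            y += s.reshape(-1, cin) @ w[i, j]
    y = y.reshape(n, ho, wo, cout)
    return (y, ctx) if keep_ctx else y


def conv2d_weight_grad(ctx, dy, w_shape):
    k, _, cin, cout = w_shape
    dy2 = dy.reshape(-1, cout)
    dw = np.empty(w_shape, dtype=dy.dtype)
    for idx in range(k * k):
        dw[idx // k, idx % k] = ctx[idx].reshape(-1, cin).T @ dy2
    return dw


def _dilate_correlate(src, w_eff, stride, anchor, out_hw):
    """Scatter ``src`` on a stride-``stride`` grid and correlate.

    Places src[i] at buffer index ``anchor + stride*i`` then runs a
    stride-1 valid correlation with ``w_eff`` (k, k, C_src, C_out), giving
    an output of spatial size ``out_hw``. This realizes both the adjoint of
    a strided convolution and the forward transposed convolution.
    """
    n, h, w, c = src.shape
    k = w_eff.shape[0]
    oh, ow = out_hw
    buf = np.zeros((n, oh + k - 1, ow + k - 1, c), dtype=src.dtype)
    buf[:, anchor:anchor + stride * (h - 1) + 1:stride,
        anchor:anchor + stride * (w - 1) + 1:stride] = src
    return conv2d(buf, w_eff, stride=1, pad=0)


def conv2d_input_grad(dy, w, stride, in_hw):
    """Gradient of conv2d w.r.t. its input (pad fixed to (k-1)//2)."""
    k = w.shape[0]
    pad = (k - 1) // 2
    # correlate the dilated upstream gradient with the flipped, transposed kernel
    w_eff = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
    return _dilate_correlate(dy, w_eff, stride, k - 1 - pad, in_hw)


def conv_transpose2d(x, w, stride=2, pad=1):
    """Transposed convolution; with k=4, stride=2, pad=1 the output side is
    exactly twice the input side."""
    k = w.shape[0]
    n, h, wd, _ = x.shape
    out_hw = (stride * h - 2 * pad + k - stride, stride * wd - 2 * pad + k - stride)
    w_eff = np.ascontiguousarray(w[::-1, ::-1])
    return _dilate_correlate(x, w_eff, stride, k - 1 - pad, out_hw)


def conv_transpose2d_input_grad(dy, w, stride=2, pad=1):
    """Adjoint of conv_transpose2d: an ordinary strided convolution of dy."""
    w_eff = np.ascontiguousarray(w.transpose(0, 1, 3, 2))  # (k,k,Cout,Cin)
    return conv2d(dy, w_eff, stride=stride, pad=pad)


def conv_transpose2d_weight_grad(x, dy, w_shape, stride=2, pad=1):
    k, _, cin, cout = w_shape
    n, h, wd, _ = x.shape
    x2 = x.reshape(-1, cin)
    dyp = np.pad(dy, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dw = np.empty(w_shape, dtype=dy.dtype)
    buf = np.empty((n, h, wd, cout), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            np.copyto(buf, _shift_view(dyp, i, j, h, wd, stride))
            dw[i, j] = x2.T @ buf.reshape(-1, cout)
    return dw


def _pool_pad(x):
    n, h, w, c = x.shape
    ph, pw = (-h) % 2, (-w) % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                   constant_values=-np.inf)
    return x


def maxpool2x2(x):
    """2x2, stride-2, ceil-mode max pooling. Returns (y, argmax) where
    argmax in {0..3} indexes the window position that won (first on ties)."""
    n, h, w, c = x.shape
    xp = _pool_pad(x)
    ho, wo = xp.shape[1] // 2, xp.shape[2] // 2
    xr = xp.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, ho, wo, 4, c)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, idx


def maxpool2x2_input_grad(dy, idx, in_hw):
    n, ho, wo, c = dy.shape
    h, w = in_hw
    dxr = np.zeros((n, ho, wo, 4, c), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    dx = dxr.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * ho, 2 * wo, c)
    return dx[:, :h, :w]
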