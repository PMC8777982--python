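"""Trainable layers with explicit forward/backward passes.

The engine is deliberately minimal: a layer caches whatever its backward
pass needs, parameters are `Param` objects (data + grad), and a model is a
fixed graph of layers wired together by the network module. Default dtype
is float32 for speed; gradient-check tests run the same code in float64.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Param:
    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = None

    @property
    def size(self) -> int:
        return self.data.size


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state to persist in checkpoints (BN moments)."""
        return {}


class Conv2d(Layer):
    """k x k convolution, 'same'-style padding giving ceil(H/stride) output.

    Bias-free by default: every 3x3 convolution here is followed by batch
    normalization, whose shift absorbs a bias exactly.
    """

    def __init__(self, cin, cout, k=3, stride=1, bias=False, *, rng, dtype=np.float32):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2
        fan_in = cin * k * k
        self.weight = Param("weight", he_uniform(rng, (k, k, cin, cout), fan_in, dtype))
        self.bias = Param("bias", np.zeros(cout, dtype=dtype)) if bias else None
        self._ctx = None
        self._in_hw = None

    def forward(self, x, training):
        self._in_hw = x.shape[1:3]
        if training:
            y, self._ctx = F.conv2d(x, self.weight.data, self.stride, self.pad,
                                    keep_ctx=True)
        else:
            y = F.conv2d(x, self.weight.data, self.stride, self.pad)
            self._ctx = None
        if self.bias is not None:
            y = y + self.bias.data
        return y

    def backward(self, dy):
        self.weight.grad = F.conv2d_weight_grad(self._ctx, dy, self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad = dy.reshape(-1, self.cout).sum(axis=0)
        self._ctx = None
        return F.conv2d_input_grad(dy, self.weight.data, self.stride, self._in_hw)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class ConvTranspose2d(Layer):
    """Kernel-4, stride-2 transposed convolution: exact x2 upsampling."""

    def __init__(self, cin, cout, k=4, stride=2, *, rng, dtype=np.float32):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, 1
        fan_in = cin * k * k
        self.weight = Param("weight", he_uniform(rng, (k, k, cin, cout), fan_in, dtype))
        self._x = None

    def forward(self, x, training):
        self._x = x if training else None
        return F.conv_transpose2d(x, self.weight.data, self.stride, self.pad)

    def backward(self, dy):
        self.weight.grad = F.conv_transpose2d_weight_grad(
            self._x, dy, self.weight.data.shape, self.stride, self.pad)
        self._x = None
        return F.conv_transpose2d_input_grad(dy, self.weight.data, self.stride, self.pad)

    def parameters(self):
        return [self.weight]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Inference uses exponentially averaged running moments; while the layer
    has never seen a training batch it falls back to the statistics of the
    batch at hand, so an untrained network still produces calibrated
    (rather than saturated) activations.
    """

    eps = 1e-5
    momentum = 0.1

    def __init__(self, c, *, dtype=np.float32):
        self.c = c
        self.gamma = Param("gamma", np.ones(c, dtype=dtype))
        self.beta = Param("beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.n_batches_tracked = 0
        self._cache = None

    def forward(self, x, training):
        if training or self.n_batches_tracked == 0:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            if training:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
                self.n_batches_tracked += 1
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        axes = (0, 1, 2)
        self.gamma.grad = (dy * xhat).sum(axis=axes)
        self.beta.grad = dy.sum(axis=axes)
        dxhat = dy * self.gamma.data
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return {
            "running_mean": self.running_mean,
            "running_var": self.running_var,
            "n_batches_tracked": np.array(self.n_batches_tracked),
        }

    def load_state(self, state):
        self.running_mean = state["running_mean"]
        self.running_var = state["running_var"]
        self.n_batches_tracked = int(state["n_batches_tracked"])


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        y = np.maximum(x, 0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, dy):
        dy = dy * self._mask
        self._mask = None
        return dy


class MaxPool2d(Layer):
    """2x2 stride-2 ceil-mode max pooling."""

    def __init__(self):
        self._idx = None
        self._in_hw = None

    def forward(self, x, training):
        self._in_hw = x.shape[1:3]
        y, idx = F.maxpool2x2(x)
        self._idx = idx if training else None
        return y

    def backward(self, dy):
        dx = F.maxpool2x2_input_grad(dy, self._idx, self._in_hw)
        self._idx = None
        return dx


class AvgPool2d(Layer):
    """2x2 stride-2 ceil-mode average pooling (config alternative to max;
    edge windows average over the cells that exist)."""

    def __init__(self):
        self._in_hw = None

    @staticmethod
    def _counts(h, w, dtype):
        ch = np.full((h + 1) // 2, 2, dtype=dtype)
        cw = np.full((w + 1) // 2, 2, dtype=dtype)
        if h % 2:
            ch[-1] = 1
        if w % 2:
            cw[-1] = 1
        return ch[:, None] * cw[None, :]

    def forward(self, x, training):
        n, h, w, c = x.shape
        self._in_hw = (h, w)
        xp = np.pad(x, ((0, 0), (0, (-h) % 2), (0, (-w) % 2), (0, 0)))
        ho, wo = xp.shape[1] // 2, xp.shape[2] // 2
        s = xp.reshape(n, ho, 2, wo, 2, c).sum(axis=(2, 4))
        return s / self._counts(h, w, x.dtype)[None, :, :, None]

    def backward(self, dy):
        h, w = self._in_hw
        n, ho, wo, c = dy.shape
        d = dy / self._counts(h, w, dy.dtype)[None, :, :, None]
        dx = np.repeat(np.repeat(d, 2, axis=1), 2, axis=2)
        return dx[:, :h, :w]


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
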