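"""Adam with global-L2 gradient clipping."""

from __future__ import annotations

import numpy as np


def global_l2_clip(params, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    sq = 0.0
    for p in params:
        g = p.grad
        sq += float(np.vdot(g, g).real)
    norm = np.sqrt(sq)
    if max_norm is not None and norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            p.grad = p.grad * scale
    return norm


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-6):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
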