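"""Dual-stream shallow segmentation networks (DSF-Net / DSA-Net).

Both networks share one encoder layout: a small input convolutional block
feeds two parallel streams — stream A downsamples with strided
convolutions (no pooling), stream B with stride-1 convolutions followed by
max pooling — and the streams are merged either by element-wise addition
(DSF, residual fusion) or depth-wise concatenation followed by a
bottleneck convolution (DSA, dense aggregation). A final convolutional
block refines the merged feature and a two-layer transposed-convolution
decoder restores the input resolution for per-pixel two-class softmax
classification (vessel vs background).

The networks are shallow by design: nine 3x3 convolutions in total and
~1.5 million trainable parameters, identical for both variants. Spatial
bookkeeping is ceil-mode throughout, so a 650x650 input reaches the merge
at 163x163.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import InputError, MergeError, StructuralValidationError
from ._nn.layers import (AvgPool2d, BatchNorm2d, Conv2d, ConvTranspose2d,
                         MaxPool2d, Param, ReLU, softmax)

__all__ = [
    "NetworkSpec",
    "SegmentationModel",
    "build_network",
    "fuse_residual",
    "aggregate_dense",
    "encoder_output_size",
    "segment",
    "count_parameters",
    "count_conv3x3",
    "save_checkpoint",
    "load_checkpoint",
]

# Reference channel schedules. Chosen so that (a) exactly nine 3x3
# convolutions exist, (b) both streams end at depth 256, and (c) the DSF
# and DSA variants have *identical* trainable-parameter totals: the DSA
# bottleneck 512->128 has the same weight count as DSF's 256->256, and the
# remaining final-block widths solve the weight- and channel-balance
# equations exactly (9*(256*192+192*64) = 9*(128*320+320*64) and
# 256+192 = 128+320).
_REFERENCE = {
    "DSF": dict(input_block=[16, 32],
                stream_a=[(64, 2), (256, 2)],
                stream_b=[(64, True), (256, True)],
                final_block=[256, 192, 64],
                decoder=[32, 16]),
    "DSA": dict(input_block=[16, 32],
                stream_a=[(64, 2), (256, 2)],
                stream_b=[(64, True), (256, True)],
                final_block=[128, 320, 64],
                decoder=[32, 16]),
}


@dataclass
class NetworkSpec:
    """Declarative description of a dual-stream network.

    ``stream_a`` entries are (width, stride); ``stream_b`` entries are
    (width, pool_after). ``variant`` selects the merge: "DSF" adds the two
    stream outputs element-wise, "DSA" concatenates them depth-wise and
    lets the first final-block convolution act as a bottleneck.
    """

    variant: str = "DSA"
    in_channels: int = 3
    n_classes: int = 2
    input_block: list = field(default_factory=lambda: list(_REFERENCE["DSA"]["input_block"]))
    stream_a: list = field(default_factory=lambda: list(_REFERENCE["DSA"]["stream_a"]))
    stream_b: list = field(default_factory=lambda: list(_REFERENCE["DSA"]["stream_b"]))
    final_block: list = field(default_factory=lambda: list(_REFERENCE["DSA"]["final_block"]))
    decoder: list = field(default_factory=lambda: list(_REFERENCE["DSA"]["decoder"]))
    pooling: str = "max"

    @classmethod
    def reference(cls, variant: str = "DSA") -> "NetworkSpec":
        v = variant.upper()
        if v not in _REFERENCE:
            raise StructuralValidationError(f"unknown variant {variant!r}; expected DSF or DSA")
        sched = _REFERENCE[v]
        return cls(variant=v,
                   input_block=list(sched["input_block"]),
                   stream_a=[list(t) for t in sched["stream_a"]],
                   stream_b=[list(t) for t in sched["stream_b"]],
                   final_block=list(sched["final_block"]),
                   decoder=list(sched["decoder"]))

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        if self.variant not in ("DSF", "DSA"):
            raise StructuralValidationError(
                f"variant must be DSF or DSA, got {self.variant!r}")
        if self.in_channels < 1 or self.n_classes < 2:
            raise StructuralValidationError("in_channels >= 1 and n_classes >= 2 required")
        stride_product = 1
        for _, s in self.stream_a:
            stride_product *= int(s)
        if stride_product != 4:
            raise StructuralValidationError(
                f"stream_a stride product must be 4 (got {stride_product}); "
                "stream A downsamples only by strided convolution")
        n_pools = sum(1 for _, pool in self.stream_b if pool)
        if n_pools != 2:
            raise StructuralValidationError(
                f"stream_b must contain exactly 2 pooling layers (got {n_pools})")
        if self.stream_a[-1][0] != self.stream_b[-1][0]:
            raise StructuralValidationError(
                "stream output depths differ "
                f"({self.stream_a[-1][0]} vs {self.stream_b[-1][0]}); "
                "the merge requires equal depths")
        n_conv3 = self.n_conv3x3()
        if n_conv3 != 9:
            raise StructuralValidationError(
                f"total 3x3 convolution count must be 9 (got {n_conv3})")
        if self.pooling not in ("max", "average"):
            raise StructuralValidationError(f"unknown pooling {self.pooling!r}")

    def n_conv3x3(self) -> int:
        return (len(self.input_block) + len(self.stream_a)
                + len(self.stream_b) + len(self.final_block))

    def merged_depth(self) -> int:
        d = self.stream_a[-1][0]
        return 2 * d if self.variant == "DSA" else d

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        return cls(**json.loads(s))


# -- feature-map ops ----------------------------------------------------------

def _check_featuremap(x, name):
    x = np.asarray(x)
    if x.ndim not in (3, 4):
        raise MergeError(f"{name} must be (H,W,C) or (N,H,W,C), got ndim {x.ndim}")
    if x.shape[-1] < 1 or x.shape[-2] < 1 or x.shape[-3] < 1:
        raise MergeError(f"{name} has a degenerate dimension: shape {x.shape}")
    return x


def fuse_residual(g, k):
    """Residual fusion: element-wise sum of the two stream outputs."""
    g, k = _check_featuremap(g, "g"), _check_featuremap(k, "k")
    if g.shape != k.shape:
        raise MergeError(f"residual fusion needs identical shapes, got {g.shape} vs {k.shape}")
    return g + k


def aggregate_dense(g, k):
    """Dense aggregation: depth-wise concatenation, g channels first."""
    g, k = _check_featuremap(g, "g"), _check_featuremap(k, "k")
    if g.shape[:-1] != k.shape[:-1]:
        raise MergeError(
            f"concatenation needs identical spatial dims, got {g.shape[:-1]} vs {k.shape[:-1]}")
    return np.concatenate([g, k], axis=-1)


def encoder_output_size(h: int, w: int) -> tuple[int, int]:
    """Spatial size of the merged encoder feature: two ceil-mode halvings.

    650x650 -> 163x163; both streams obey this identically (stride-2
    convolution and 2x2 ceil-mode pooling halve the same way).
    """
    if h < 4 or w < 4:
        raise InputError(f"input spatial dims must be >= 4, got {(h, w)}")
    return (math.ceil(math.ceil(h / 2) / 2), math.ceil(math.ceil(w / 2) / 2))


# -- the model ----------------------------------------------------------------

def _conv_bn_relu(cin, cout, stride, rng, dtype):
    return [Conv2d(cin, cout, 3, stride, rng=rng, dtype=dtype),
            BatchNorm2d(cout, dtype=dtype), ReLU()]


class SegmentationModel:
    """A built dual-stream network: weights plus the forward/backward graph.

    Use :func:`build_network` to construct one; :func:`segment` for
    inference; ``fit`` lives in :mod:`vesselseg.train`.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        c = spec.in_channels
        self.input_block = []
        for width in spec.input_block:
            self.input_block += _conv_bn_relu(c, width, 1, rng, dtype)
            c = width
        c_trunk = c

        self.stream_a = []
        c = c_trunk
        for width, stride in spec.stream_a:
            self.stream_a += _conv_bn_relu(c, width, int(stride), rng, dtype)
            c = width

        self.stream_b = []
        c = c_trunk
        for width, pool in spec.stream_b:
            self.stream_b += _conv_bn_relu(c, width, 1, rng, dtype)
            if pool:
                self.stream_b.append(
                    MaxPool2d() if spec.pooling == "max" else AvgPool2d())
            c = width

        c = spec.merged_depth()
        self.final_block = []
        for width in spec.final_block:
            self.final_block += _conv_bn_relu(c, width, 1, rng, dtype)
            c = width

        self.decoder = []
        for width in spec.decoder:
            self.decoder += [ConvTranspose2d(c, width, rng=rng, dtype=dtype),
                             BatchNorm2d(width, dtype=dtype), ReLU()]
            c = width

        self.classifier = Conv2d(c, spec.n_classes, k=1, stride=1, bias=True,
                                 rng=rng, dtype=dtype)
        self._crop = None
        self._in_hw = None

    # ---- plumbing
    def _layers(self):
        return (self.input_block + self.stream_a + self.stream_b
                + self.final_block + self.decoder + [self.classifier])

    def parameters(self) -> list[Param]:
        out = []
        for layer in self._layers():
            out += layer.parameters()
        return out

    def conv3x3_layers(self):
        return [l for l in self._layers() if isinstance(l, Conv2d) and l.k == 3]

    # ---- forward / backward
    def forward_logits(self, x, training=False):
        """x: (N,H,W,Cin) float in [0,1] -> logits (N,H,W,n_classes)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[-1] != self.spec.in_channels:
            raise InputError(
                f"expected (N,H,W,{self.spec.in_channels}) input, got shape {x.shape}")
        if x.shape[1] < 4 or x.shape[2] < 4:
            raise InputError(f"spatial dims must be >= 4, got {x.shape[1:3]}")
        self._in_hw = h, w = x.shape[1], x.shape[2]

        for layer in self.input_block:
            x = layer.forward(x, training)
        ga = x
        for layer in self.stream_a:
            ga = layer.forward(ga, training)
        kb = x
        for layer in self.stream_b:
            kb = layer.forward(kb, training)

        if ga.shape[1:3] != kb.shape[1:3]:
            raise MergeError(
                f"stream outputs disagree spatially: {ga.shape[1:3]} vs {kb.shape[1:3]}")
        if self.spec.variant == "DSF":
            m = ga + kb
        else:
            m = np.concatenate([ga, kb], axis=-1)
        self._split = ga.shape[-1]

        for layer in self.final_block:
            m = layer.forward(m, training)
        for layer in self.decoder:
            m = layer.forward(m, training)

        dh, dw = m.shape[1], m.shape[2]
        oy, ox = (dh - h) // 2, (dw - w) // 2
        self._crop = (oy, ox, dh, dw)
        m = m[:, oy:oy + h, ox:ox + w]
        return self.classifier.forward(m, training)

    def backward(self, dlogits):
        d = self.classifier.backward(dlogits)
        oy, ox, dh, dw = self._crop
        h, w = self._in_hw
        full = np.zeros((d.shape[0], dh, dw, d.shape[-1]), dtype=d.dtype)
        full[:, oy:oy + h, ox:ox + w] = d
        d = full
        for layer in reversed(self.decoder):
            d = layer.backward(d)
        for layer in reversed(self.final_block):
            d = layer.backward(d)
        if self.spec.variant == "DSF":
            da, db = d, d
        else:
            da, db = d[..., :self._split], d[..., self._split:]
        for layer in reversed(self.stream_a):
            da = layer.backward(da)
        for layer in reversed(self.stream_b):
            db = layer.backward(db)
        d = da + db
        for layer in reversed(self.input_block):
            d = layer.backward(d)
        return d

    def predict_proba(self, x):
        """Per-pixel class probabilities (N,H,W,n_classes), rows sum to 1."""
        return softmax(self.forward_logits(x, training=False))


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> SegmentationModel:
    """Build a model from a validated spec (raises StructuralValidationError
    naming the violated invariant otherwise)."""
    return SegmentationModel(spec, seed=seed, dtype=dtype)


def count_parameters(model: SegmentationModel) -> int:
    """Exact number of trainable scalars (conv/transposed-conv weights,
    biases, BN scale and shift)."""
    return sum(p.size for p in model.parameters())


def count_conv3x3(model: SegmentationModel) -> int:
    """Number of 3x3 convolution layers (1x1 classifier and transposed
    convolutions excluded)."""
    return len(model.conv3x3_layers())


def segment(model: SegmentationModel, image) -> tuple[np.ndarray, np.ndarray]:
    """Segment one RGB image (H,W,3, uint8 or float in [0,1]).

    Returns ``(probability_map, mask)``: (H,W,2) softmax probabilities
    (channel 0 background, channel 1 vessel) and the argmax binary mask
    with vessel=1. Probability ties resolve to background.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != model.spec.in_channels:
        raise InputError(f"expected (H,W,{model.spec.in_channels}) image, got {img.shape}")
    x = img.astype(model.dtype)
    if img.dtype == np.uint8:
        x = x / 255.0
    prob = model.predict_proba(x[None])[0]
    mask = (prob[..., 1] > prob[..., 0]).astype(np.uint8)
    return prob, mask


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path) -> None:
    """Self-describing checkpoint: spec JSON + every array, bit-exact."""
    arrays = {"__spec__": np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8)}
    for i, layer in enumerate(model._layers()):
        for p in layer.parameters():
            arrays[f"layer{i}.{p.name}"] = p.data
        for name, arr in layer.state_arrays().items():
            arrays[f"layer{i}.{name}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path) as data:
        spec = NetworkSpec.from_json(bytes(data["__spec__"]).decode())
        model = SegmentationModel(spec)
        for i, layer in enumerate(model._layers()):
            for p in layer.parameters():
                p.data = data[f"layer{i}.{p.name}"]
            state = {name: data[f"layer{i}.{name}"] for name in layer.state_arrays()}
            if state:
                layer.load_state(state)
    return model
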