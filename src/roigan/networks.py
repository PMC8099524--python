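"""Network architectures: regional feature extraction block (RFB), generator,
discriminator.

Architectures are declared as :class:`NetworkSpec` — an ordered list of
:class:`LayerSpec` with hard shape contracts — and executed by
:class:`Network`, which initializes parameters and runs forward/backward
passes over the :mod:`roigan.nn` primitives.  Declared specs are JSON
(de)serializable so a checkpoint always carries an auditable description of
the model that produced it.

Shape anchors honored by the generator plan (for a 256x256 input): the
3-pixel mirror pad yields 262x262, the encoder bottleneck after the third
convolution is a 128-channel 64x64 map, and the decoder restores the input
size exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

INSTANCE_NORM_EPS = 1e-5
WEIGHT_INIT_SD = 0.02  # Gaussian init, cycleGAN convention


@dataclass
class LayerSpec:
    """One layer of a network: kind plus the hyper-parameters it needs."""

    kind: str  # mirror_pad | conv | deconv | instance_norm | activation | flatten | dense | concat_fusion
    kernel: int | None = None
    stride: int = 1
    out_channels: int | None = None
    pad: int = 0
    activation_name: str | None = None
    slope: float = 0.2
    output_padding: int = 0
    skip_from: int | None = None  # layer index whose output a concat_fusion joins

    def __post_init__(self):
        if self.kind in ("conv", "deconv", "concat_fusion"):
            if not (self.kernel and self.kernel > 0):
                raise ValueError(f"{self.kind}: kernel must be positive")
            if not (self.out_channels and self.out_channels > 0):
                raise ValueError(f"{self.kind}: out_channels must be positive")
            if self.stride < 1:
                raise ValueError(f"{self.kind}: stride must be positive")
        if self.kind == "activation" and self.activation_name == "leaky_relu":
            if not 0 < self.slope < 1:
                raise ValueError("leaky_relu slope must lie in (0,1)")


@dataclass
class NetworkSpec:
    name: str
    layers: list[LayerSpec]
    input_channels: int
    input_size: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "input_channels": self.input_channels,
                "input_size": self.input_size,
                "layers": [asdict(l) for l in self.layers],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            layers=[LayerSpec(**l) for l in d["layers"]],
            input_channels=d["input_channels"],
            input_size=d["input_size"],
        )

    def layer_census(self) -> dict:
        census: dict[str, int] = {}
        for l in self.layers:
            census[l.kind] = census.get(l.kind, 0) + 1
        return census


def shape_trace(spec: NetworkSpec) -> list[tuple]:
    """Per-layer output shapes ((C,H,W), or (n,) after flatten/dense).

    Raises ValueError if any layer's shape arithmetic leaves a non-positive
    or fractional dimension, which enforces the spec invariant that composing
    the layers over input_size is well defined.
    """
    shapes: list[tuple] = []
    c, h, w = spec.input_channels, spec.input_size, spec.input_size
    flat = None
    for i, l in enumerate(spec.layers):
        if l.kind == "mirror_pad":
            h, w = h + 2 * l.pad, w + 2 * l.pad
        elif l.kind == "conv":
            nh = (h + 2 * l.pad - l.kernel) // l.stride + 1
            nw = (w + 2 * l.pad - l.kernel) // l.stride + 1
            if nh <= 0 or nw <= 0 or h + 2 * l.pad < l.kernel:
                raise ValueError(f"layer {i} ({spec.name}): conv shape arithmetic "
                                 f"fails at input {h}x{w}")
            c, h, w = l.out_channels, nh, nw
        elif l.kind == "deconv":
            h = (h - 1) * l.stride - 2 * l.pad + l.kernel + l.output_padding
            w = (w - 1) * l.stride - 2 * l.pad + l.kernel + l.output_padding
            c = l.out_channels
        elif l.kind == "concat_fusion":
            src = shapes[l.skip_from]
            if src[1:] != (h, w):
                raise ValueError(f"layer {i}: skip source spatial dims {src[1:]} "
                                 f"!= current {(h, w)}")
            c = l.out_channels
        elif l.kind in ("instance_norm", "activation"):
            pass
        elif l.kind == "flatten":
            flat = c * h * w
            shapes.append((flat,))
            continue
        elif l.kind == "dense":
            flat = l.out_channels
            shapes.append((flat,))
            continue
        else:
            raise ValueError(f"unknown layer kind {l.kind!r}")
        if flat is not None and l.kind == "activation":
            shapes.append((flat,))
            continue
        shapes.append((c, h, w))
    return shapes


# ---------------------------------------------------------------------------
# builders


def build_rfb_spec(image_size: int, feature_channels: int = 8) -> NetworkSpec:
    """Regional feature extraction block: 2 mirror-pad, 3 conv (each with
    instance norm + ReLU), 1 deconv restoring the input size."""
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    if image_size % 2:
        raise ValueError("image_size must be even for the stride plan")
    layers = [
        LayerSpec("mirror_pad", pad=1),
        LayerSpec("conv", kernel=3, stride=1, out_channels=16),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("conv", kernel=3, stride=2, out_channels=32, pad=1),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("mirror_pad", pad=1),
        LayerSpec("conv", kernel=3, stride=1, out_channels=64),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("deconv", kernel=3, stride=2, out_channels=feature_channels,
                  pad=1, output_padding=1),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
    ]
    spec = NetworkSpec("rfb", layers, input_channels=1, input_size=image_size)
    shape_trace(spec)
    return spec


def build_generator_spec(image_size: int, in_channels: int,
                         out_channels: int = 1, name: str = "generator_G"
                         ) -> NetworkSpec:
    """Generator: 3-pixel mirror pad, 4 conv layers (encoder + bottleneck),
    2 deconv layers, 2 concat-fusion skip layers, sigmoid output in [0,1].

    Channel plan 32/64/128 with strides (1,2,2,1): at 256x256 this gives the
    262x262 padded map and the 128-channel 64x64 bottleneck.
    """
    if image_size % 4:
        raise ValueError("image_size must be divisible by 4")
    layers = [
        LayerSpec("mirror_pad", pad=3),
        LayerSpec("conv", kernel=7, stride=1, out_channels=32),          # 1: S, 32
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),                 # 3: skip a
        LayerSpec("conv", kernel=3, stride=2, out_channels=64, pad=1),   # 4: S/2, 64
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),                 # 6: skip b
        LayerSpec("conv", kernel=3, stride=2, out_channels=128, pad=1),  # 7: S/4, 128
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),                 # 9: bottleneck
        LayerSpec("conv", kernel=3, stride=1, out_channels=128, pad=1),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("deconv", kernel=3, stride=2, out_channels=64, pad=1,
                  output_padding=1),                                     # 13: S/2
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("concat_fusion", kernel=1, out_channels=64, skip_from=6),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("deconv", kernel=3, stride=2, out_channels=32, pad=1,
                  output_padding=1),                                     # 19: S
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("concat_fusion", kernel=1, out_channels=32, skip_from=3),
        LayerSpec("instance_norm"),
        LayerSpec("activation", activation_name="relu"),
        LayerSpec("conv", kernel=7, stride=1, out_channels=out_channels, pad=3),
        LayerSpec("activation", activation_name="sigmoid"),
    ]
    spec = NetworkSpec(name, layers, input_channels=in_channels,
                       input_size=image_size)
    trace = shape_trace(spec)
    assert trace[-1] == (out_channels, image_size, image_size)
    return spec


def build_discriminator_spec(image_size: int, in_channels: int = 1,
                             name: str = "discriminator_Dy") -> NetworkSpec:
    """Discriminator: 4 strided conv layers with leaky-ReLU, flatten, dense
    to one unit, sigmoid — a single realness score in (0,1) per image."""
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    if image_size % 16:
        raise ValueError("image_size must be divisible by 16")
    layers = []
    for ch in (64, 128, 256, 512):
        layers.append(LayerSpec("conv", kernel=4, stride=2, out_channels=ch, pad=1))
        layers.append(LayerSpec("activation", activation_name="leaky_relu", slope=0.2))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", out_channels=1),
        LayerSpec("activation", activation_name="sigmoid"),
    ]
    spec = NetworkSpec(name, layers, input_channels=in_channels,
                       input_size=image_size)
    shape_trace(spec)
    return spec


# ---------------------------------------------------------------------------
# execution


class Network:
    """Executor for a NetworkSpec: parameter init, forward, backward.

    Parameters live in a flat dict ``{"<idx>.w": array, "<idx>.b": array}``
    keyed by layer index, so optimizers and checkpoints treat them uniformly.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.shapes = shape_trace(spec)

    def _in_shape(self, i: int):
        if i == 0:
            return (self.spec.input_channels, self.spec.input_size,
                    self.spec.input_size)
        return self.shapes[i - 1]

    def init_params(self, rng: np.random.Generator, dtype=nn.DTYPE,
                    zero: bool = False) -> dict:
        params = {}
        for i, l in enumerate(self.spec.layers):
            cin = self._in_shape(i)[0]
            if l.kind == "conv":
                shape = (l.out_channels, cin, l.kernel, l.kernel)
            elif l.kind == "deconv":
                shape = (cin, l.out_channels, l.kernel, l.kernel)
            elif l.kind == "concat_fusion":
                c_skip = self.shapes[l.skip_from][0]
                shape = (l.out_channels, cin + c_skip, l.kernel, l.kernel)
            elif l.kind == "dense":
                shape = (l.out_channels, self._in_shape(i)[0])
            else:
                continue
            if zero:
                params[f"{i}.w"] = np.zeros(shape, dtype=dtype)
            else:
                params[f"{i}.w"] = (WEIGHT_INIT_SD
                                    * rng.standard_normal(shape)).astype(dtype)
            params[f"{i}.b"] = np.zeros(l.out_channels, dtype=dtype)
        return params

    def forward(self, params: dict, x: np.ndarray, record_shapes: bool = False):
        """Run the network. Returns (output, tape); the tape is consumed by
        :meth:`backward`. Raises ValueError naming the offending layer on a
        shape mismatch."""
        expected = (self.spec.input_channels, self.spec.input_size,
                    self.spec.input_size)
        if x.shape != expected:
            raise ValueError(
                f"{self.spec.name}: input shape {x.shape} != expected {expected}")
        outputs: list[np.ndarray] = []
        caches: list = []
        cur = x
        for i, l in enumerate(self.spec.layers):
            if l.kind == "mirror_pad":
                cur, cache = nn.mirror_pad_forward(cur, l.pad)
            elif l.kind == "conv":
                cur, cache = nn.conv2d_forward(
                    cur, params[f"{i}.w"], params[f"{i}.b"], l.stride, l.pad)
            elif l.kind == "deconv":
                cur, cache = nn.deconv2d_forward(
                    cur, params[f"{i}.w"], params[f"{i}.b"], l.stride, l.pad,
                    l.output_padding)
            elif l.kind == "instance_norm":
                cur, cache = nn.instance_norm_forward(cur, INSTANCE_NORM_EPS)
            elif l.kind == "activation":
                cur, cache = nn.activation_forward(cur, l.activation_name, l.slope)
            elif l.kind == "flatten":
                cache = cur.shape
                cur = cur.ravel()
            elif l.kind == "dense":
                cur, cache = nn.dense_forward(cur, params[f"{i}.w"], params[f"{i}.b"])
            elif l.kind == "concat_fusion":
                joined = np.concatenate([cur, outputs[l.skip_from]], axis=0)
                cur, cache = nn.conv2d_forward(
                    joined, params[f"{i}.w"], params[f"{i}.b"], 1, 0)
            else:
                raise ValueError(f"layer {i}: unknown kind {l.kind!r}")
            if l.kind not in ("flatten", "dense") and cur.ndim == 3:
                want = self.shapes[i]
                if cur.shape != want:
                    raise ValueError(
                        f"{self.spec.name} layer {i} ({l.kind}): produced "
                        f"{cur.shape}, expected {want}")
            outputs.append(cur)
            caches.append(cache)
        tape = (outputs, caches)
        return cur, tape

    def backward(self, params: dict, tape, grad_out: np.ndarray):
        """Backpropagate grad_out through the taped forward pass.
        Returns (grad_input, grads dict keyed like params)."""
        outputs, caches = tape
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        skip_grads: dict[int, np.ndarray] = {}
        g = grad_out
        for i in range(len(self.spec.layers) - 1, -1, -1):
            l = self.spec.layers[i]
            if i in skip_grads:
                g = g + skip_grads.pop(i)
            if l.kind == "mirror_pad":
                g = nn.mirror_pad_backward(g, caches[i])
            elif l.kind == "conv":
                g, gw, gb = nn.conv2d_backward(g, caches[i], params[f"{i}.w"],
                                               l.stride, l.pad)
                grads[f"{i}.w"] += gw
                grads[f"{i}.b"] += gb
            elif l.kind == "deconv":
                g, gw, gb = nn.deconv2d_backward(g, caches[i], params[f"{i}.w"],
                                                 l.stride, l.pad, l.output_padding)
                grads[f"{i}.w"] += gw
                grads[f"{i}.b"] += gb
            elif l.kind == "instance_norm":
                g = nn.instance_norm_backward(g, caches[i])
            elif l.kind == "activation":
                g = nn.activation_backward(g, caches[i])
            elif l.kind == "flatten":
                g = g.reshape(caches[i])
            elif l.kind == "dense":
                g, gw, gb = nn.dense_backward(g, caches[i], params[f"{i}.w"])
                grads[f"{i}.w"] += gw
                grads[f"{i}.b"] += gb
            elif l.kind == "concat_fusion":
                gj, gw, gb = nn.conv2d_backward(g, caches[i], params[f"{i}.w"], 1, 0)
                grads[f"{i}.w"] += gw
                grads[f"{i}.b"] += gb
                c_main = self.shapes[i - 1][0] if i else self.spec.input_channels
                g = gj[:c_main]
                src = l.skip_from
                prev = skip_grads.get(src)
                skip_grads[src] = gj[c_main:] if prev is None else prev + gj[c_main:]
        return g, grads


def forward(spec: NetworkSpec, params: dict, x: np.ndarray) -> np.ndarray:
    """Functional forward pass. Accepts (C,H,W) or a batch (N,C,H,W); batched
    input returns the stacked per-sample outputs."""
    net = Network(spec)
    if x.ndim == 4:
        return np.stack([net.forward(params, xi)[0] for xi in x])
    return net.forward(params, x)[0]


def fuse_regional_features(image: np.ndarray, rfb_features: np.ndarray) -> np.ndarray:
    """Channel-concatenate image (H,W) or (1,H,W) with RFB feature maps
    (F,H,W); channel 0 of the result is the unmodified image."""
    if image.ndim == 2:
        image = image[None]
    if image.shape[1:] != rfb_features.shape[1:]:
        raise ValueError(
            f"spatial dims differ: image {image.shape[1:]} vs features "
            f"{rfb_features.shape[1:]}")
    return np.concatenate([image, rfb_features], axis=0)
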