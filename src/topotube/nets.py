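"""3D U-Net backbone and the cascaded segmentation→skeletonization model.

The backbone follows the vessel-segmentation configuration: an encoder of
``depth`` resolution levels below the input, two 3×3×3 convolutions per
stage with instance normalization and leaky-rectifier activations,
stride-2 convolutions for downsampling (channels doubling per level),
a mirrored decoder with stride-2 transposed convolutions and skip
connections by channel concatenation, and a single-channel sigmoid head.

The cascade stacks two such U-Nets: the segmentation network maps the
image to a soft vessel mask; the skeletonization network maps the image
concatenated with that predicted mask to a soft centerline. When the
skeletonization network is frozen its parameters receive no updates while
gradients still flow *through* it into the segmentation network — the
mechanism that lets a centerline-overlap loss supervise the segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, conv3d, conv_transpose3d, instance_norm

__all__ = ["UNetSpec", "CascadeSpec", "UNet3D", "CascadedUNet", "build_unet", "cascaded_forward"]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture contract of the backbone.

    ``depth`` is the number of resolution levels below the input (every
    spatial input dimension must be divisible by ``2**depth``);
    ``max_channels`` optionally caps the doubling channel schedule.
    Normalization is fixed to instance norm, activation to leaky-rectifier
    (slope 0.01), downsampling to stride-2 convolution.
    """

    in_channels: int = 1
    depth: int = 4
    base_channels: int = 32
    max_channels: int | None = None
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.in_channels < 1 or self.depth < 1 or self.base_channels < 1:
            raise ValueError("in_channels, depth and base_channels must be >= 1")

    def channels(self, level: int) -> int:
        c = self.base_channels * 2**level
        return min(c, self.max_channels) if self.max_channels else c


@dataclass(frozen=True)
class CascadeSpec:
    """The two-network cascade: the skeletonization net consumes the image
    plus the predicted segmentation, hence one extra input channel."""

    seg_net: UNetSpec
    skel_net: UNetSpec
    freeze_skel: bool = True

    def __post_init__(self):
        if self.skel_net.in_channels != self.seg_net.in_channels + 1:
            raise ValueError(
                "skel_net.in_channels must equal seg_net.in_channels + 1 "
                "(image + predicted segmentation)"
            )


# ---------------------------------------------------------------------------
# parameter containers


class _Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, np.float32).copy()

    def set_trainable(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag


class _ConvBlock(_Module):
    """Two 3×3×3 conv + instance norm + leaky-rectifier layers."""

    def __init__(self, c_in, c_out, slope, rng):
        self.slope = slope
        self.layers = []
        for ci, co in ((c_in, c_out), (c_out, c_out)):
            w = Tensor(_he(rng, (co, ci, 3, 3, 3)), requires_grad=True)
            b = Tensor(np.zeros(co, np.float32), requires_grad=True)
            gamma = Tensor(np.ones(co, np.float32), requires_grad=True)
            beta = Tensor(np.zeros(co, np.float32), requires_grad=True)
            self.layers.append((w, b, gamma, beta))

    def __call__(self, x):
        for w, b, gamma, beta in self.layers:
            x = instance_norm(conv3d(x, w, b), gamma, beta).leaky_relu(self.slope)
        return x

    def parameters(self):
        return [t for layer in self.layers for t in layer]


def _he(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class UNet3D(_Module):
    """The backbone network. Weights are seeded through ``rng``."""

    def __init__(self, spec: UNetSpec, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        s = spec.negative_slope
        ch = [spec.channels(l) for l in range(spec.depth + 1)]
        self.enc = [_ConvBlock(spec.in_channels, ch[0], s, rng)]
        self.down = []
        for l in range(1, spec.depth + 1):
            w = Tensor(_he(rng, (ch[l], ch[l - 1], 3, 3, 3)), requires_grad=True)
            b = Tensor(np.zeros(ch[l], np.float32), requires_grad=True)
            self.down.append((w, b))
            self.enc.append(_ConvBlock(ch[l], ch[l], s, rng))
        self.up = []
        self.dec = []
        for l in range(spec.depth, 0, -1):
            w = Tensor(_he(rng, (ch[l], ch[l - 1], 2, 2, 2)), requires_grad=True)
            b = Tensor(np.zeros(ch[l - 1], np.float32), requires_grad=True)
            self.up.append((w, b))
            self.dec.append(_ConvBlock(2 * ch[l - 1], ch[l - 1], s, rng))
        self.head_w = Tensor(_he(rng, (1, ch[0], 1, 1, 1)), requires_grad=True)
        self.head_b = Tensor(np.zeros(1, np.float32), requires_grad=True)

    @property
    def bottleneck_channels(self) -> int:
        return self.spec.channels(self.spec.depth)

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim == 3:
            x = Tensor(x.data[None, None], requires_grad=x.requires_grad)
        sp = x.shape[2:]
        div = 2**self.spec.depth
        if any(s % div for s in sp):
            raise ValueError(f"spatial shape {sp} not divisible by 2^depth = {div}")
        skips = []
        h = self.enc[0](x)
        for (w, b), block in zip(self.down, self.enc[1:]):
            skips.append(h)
            h = conv3d(h, w, b, stride=2)
            h = block(h)
        for (w, b), block, skip in zip(self.up, self.dec, reversed(skips)):
            h = conv_transpose3d(h, w, b)
            h = block(concat([skip, h], axis=1))
        return conv3d(h, self.head_w, self.head_b).sigmoid()

    def parameters(self):
        out = []
        for block in self.enc:
            out += block.parameters()
        for w, b in self.down:
            out += [w, b]
        for w, b in self.up:
            out += [w, b]
        for block in self.dec:
            out += block.parameters()
        out += [self.head_w, self.head_b]
        return out


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet3D:
    """Construct a seeded backbone from its architecture contract."""
    return UNet3D(spec, np.random.default_rng(seed))


class CascadedUNet(_Module):
    """Segmentation network followed by the skeletonization network."""

    def __init__(self, spec: CascadeSpec, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.seg_net = UNet3D(spec.seg_net, rng)
        self.skel_net = UNet3D(spec.skel_net, rng)
        if spec.freeze_skel:
            self.skel_net.set_trainable(False)

    def __call__(self, image) -> tuple[Tensor, Tensor]:
        if not isinstance(image, Tensor):
            image = Tensor(image)
        if image.data.ndim == 3:
            image = Tensor(image.data[None, None])
        s_p = self.seg_net(image)
        c_p = self.skel_net(concat([image, s_p], axis=1))
        return s_p, c_p

    def parameters(self):
        return self.seg_net.parameters() + self.skel_net.parameters()

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]


def cascaded_forward(image, model: CascadedUNet) -> tuple[Tensor, Tensor]:
    """Run the cascade: S_P = seg(image); C_P = skel(concat(image, S_P))."""
    return model(image)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: _Module, spec, extra: dict | None = None):
    """Standard container (numpy .npz) plus a JSON sidecar with the spec."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_dict())}
    np.savez(path, **arrays)
    side = {"spec": _spec_dict(spec), "n_params": len(arrays)}
    if extra:
        side.update(extra)
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=2)


def _spec_dict(spec):
    if isinstance(spec, CascadeSpec):
        return {
            "seg_net": asdict(spec.seg_net),
            "skel_net": asdict(spec.skel_net),
            "freeze_skel": spec.freeze_skel,
        }
    return asdict(spec)


def load_checkpoint(path, model: _Module):
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
        arrays = [z[f"p{i}"] for i in range(len(z.files))]
    model.load_state_dict(arrays)
    return model
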