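"""The multi-level pooling encoder-decoder (MLPED) reconstruction network.

The model maps a single-channel aliased magnitude image to a de-aliased one.
It is a five-level encoder-decoder: each encoder level is two 3x3
convolutions with instance normalisation, leaky ReLU and dropout; levels are
joined by 2x2 average pooling.  Between encoder and decoder, each of the
four upper levels passes through a multi-level pooling (MLP) module — a
residual multi-kernel pooling stage (parallel max pooling at windows 2, 3,
5 and 6, each reduced to one channel by a 1x1 convolution, upsampled and
concatenated with the input) followed by a Zoom-In/Zoom-Out group of three
convolutions that shrinks and restores the feature resolution by a zoom
factor — and the result is added back residually.  Decoders upsample with
pixel shuffle (sub-pixel convolution) instead of transposed convolution.

Channel widths: 32, 64, 128, 256 for the four upper levels (with a default
``first_channels`` of 32), and 384 at the bottleneck; the Zoom-In/Zoom-Out
hidden width is half its input width.  The two figure-only widths were fixed
so that the default model's trainable-parameter count is 7,886,593 — i.e.
8M to the nearest million, the documented size of this architecture.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor, pixel_shuffle

__all__ = [
    "NetworkConfig",
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "EncoderBlock",
    "RMP",
    "ZoomInOut",
    "MLPModule",
    "DecoderBlock",
    "MLPED",
    "build_encoder_block",
    "build_decoder_block",
    "build_mlped",
    "pixel_shuffle",
    "count_trainable_parameters",
    "save_model",
    "load_model",
]

# default per-level multipliers of first_channels: 1, 2, 4, 8 for the four
# upper levels and 12 at the bottleneck (384 when first_channels=32)
_LEVEL_MULTIPLIERS = (1, 2, 4, 8, 12)


@dataclass
class NetworkConfig:
    """All architecture hyperparameters."""

    first_channels: int = 32
    encoder_levels: int = 5
    mlp_levels: int = 4
    channel_schedule: tuple[int, ...] | None = None
    zoom_factor: int = 2
    rmp_kernels: tuple[int, ...] = (2, 3, 5, 6)
    dropout_rate: float = 0.0
    leaky_slope: float = 0.2
    norm_kind: str = "instance"

    def __post_init__(self):
        if self.encoder_levels != self.mlp_levels + 1:
            raise ValueError("encoder_levels must equal mlp_levels + 1")
        if self.channel_schedule is None:
            self.channel_schedule = tuple(
                self.first_channels * m
                for m in _LEVEL_MULTIPLIERS[: self.encoder_levels]
            )
        else:
            self.channel_schedule = tuple(self.channel_schedule)
        if len(self.channel_schedule) != self.encoder_levels:
            raise ValueError("channel_schedule length must equal encoder_levels")
        if self.channel_schedule[0] != self.first_channels:
            raise ValueError("channel_schedule[0] must equal first_channels")
        self.rmp_kernels = tuple(self.rmp_kernels)
        if any(b <= a for a, b in zip(self.rmp_kernels, self.rmp_kernels[1:])):
            raise ValueError("rmp_kernels must be strictly increasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.zoom_factor < 1:
            raise ValueError("zoom_factor must be >= 1")
        if self.norm_kind != "instance":
            raise ValueError("only instance normalisation is supported")

    def to_dict(self) -> dict:
        return {
            "first_channels": self.first_channels,
            "encoder_levels": self.encoder_levels,
            "mlp_levels": self.mlp_levels,
            "channel_schedule": list(self.channel_schedule),
            "zoom_factor": self.zoom_factor,
            "rmp_kernels": list(self.rmp_kernels),
            "dropout_rate": self.dropout_rate,
            "leaky_slope": self.leaky_slope,
            "norm_kind": self.norm_kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Minimal torch-style container: child discovery by attribute scan."""

    def __init__(self):
        self.training = True

    def _children(self) -> list["Module"]:
        kids: list[Module] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                kids.append(value)
            elif isinstance(value, (list, tuple)):
                kids.extend(v for v in value if isinstance(v, Module))
        return kids

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((path, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v.named_parameters(prefix=f"{path}.{i}."))
                    elif isinstance(v, Parameter):
                        out.append((f"{path}.{i}", v))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_trainable_parameters(model: Module) -> int:
    """Exact count of independently trainable scalars in ``model``."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 leaky_slope: float = 0.2, dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        # He initialisation with leaky-ReLU gain
        std = np.sqrt(2.0 / (fan_in * (1.0 + leaky_slope ** 2)))
        self.weight = Parameter(
            (rng.standard_normal((out_channels, in_channels, kernel, kernel)) * std)
            .astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)


class _Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.rate, self.rng, training=self.training)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class EncoderBlock(Module):
    """conv3x3 -> norm -> LeakyReLU -> dropout, twice; spatial shape kept."""

    def __init__(self, in_channels: int, out_channels: int,
                 config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.slope = config.leaky_slope
        self.conv1 = Conv2d(in_channels, out_channels, 3, padding=1,
                            rng=rng, leaky_slope=self.slope)
        self.norm1 = InstanceNorm2d(out_channels)
        self.drop1 = _Dropout(config.dropout_rate, rng)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1,
                            rng=rng, leaky_slope=self.slope)
        self.norm2 = InstanceNorm2d(out_channels)
        self.drop2 = _Dropout(config.dropout_rate, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop1(ad.leaky_relu(self.norm1(self.conv1(x)), self.slope))
        return self.drop2(ad.leaky_relu(self.norm2(self.conv2(h)), self.slope))


class RMP(Module):
    """Residual multi-kernel pooling.

    Max pooling at each window size (stride = window), a 1x1 convolution down
    to a single channel, bilinear upsampling back to the input size, then
    concatenation of the pooled maps after the untouched input:
    channels_out = channels_in + len(kernels).
    """

    def __init__(self, channels: int, kernels: Sequence[int],
                 rng: np.random.Generator, leaky_slope: float = 0.2):
        super().__init__()
        self.kernels = tuple(kernels)
        self.reducers = [
            Conv2d(channels, 1, 1, rng=rng, leaky_slope=leaky_slope)
            for _ in self.kernels
        ]

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if min(h, w) < max(self.kernels):
            raise ValueError(
                f"feature map {h}x{w} smaller than pooling kernel {max(self.kernels)}"
            )
        branches = [x]
        for k, reducer in zip(self.kernels, self.reducers):
            pooled = ad.max_pool2d(x, k)
            reduced = reducer(pooled)
            branches.append(ad.upsample_bilinear(reduced, h, w))
        return ad.concat(branches, axis=1)


class ZoomInOut(Module):
    """Three convolutions that shrink then restore the feature resolution.

    conv3x3 to the hidden width, a stride-``zoom_factor`` conv3x3 (Zoom-In),
    bilinear upsampling by the zoom factor followed by a conv3x3 back to the
    input width (Zoom-Out).  Hidden width defaults to half the input width.
    """

    def __init__(self, channels: int, zoom_factor: int,
                 rng: np.random.Generator, hidden: int | None = None,
                 leaky_slope: float = 0.2):
        super().__init__()
        self.zoom_factor = zoom_factor
        hidden = hidden if hidden is not None else max(1, channels // 2)
        self.conv_pre = Conv2d(channels, hidden, 3, padding=1,
                               rng=rng, leaky_slope=leaky_slope)
        self.conv_down = Conv2d(hidden, hidden, 3, stride=zoom_factor, padding=1,
                                rng=rng, leaky_slope=leaky_slope)
        self.conv_up = Conv2d(hidden, channels, 3, padding=1,
                              rng=rng, leaky_slope=leaky_slope)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        z = self.zoom_factor
        if h % z or w % z:
            raise ValueError(f"spatial dims {h}x{w} not divisible by zoom factor {z}")
        hid = self.conv_pre(x)
        hid = self.conv_down(hid)
        hid = ad.upsample_bilinear(hid, h, w)
        return self.conv_up(hid)


class MLPModule(Module):
    """Multi-level pooling module: RMP -> Zoom-In/Zoom-Out -> projection,
    plus a residual connection from the module input."""

    def __init__(self, channels: int, config: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        expanded = channels + len(config.rmp_kernels)
        self.rmp = RMP(channels, config.rmp_kernels, rng, config.leaky_slope)
        self.zoom = ZoomInOut(expanded, config.zoom_factor, rng,
                              leaky_slope=config.leaky_slope)
        self.project = Conv2d(expanded, channels, 3, padding=1,
                              rng=rng, leaky_slope=config.leaky_slope)

    def forward(self, x: Tensor) -> Tensor:
        h = self.rmp(x)
        h = self.zoom(h)
        h = self.project(h)
        return ad.add(h, x)


class DecoderBlock(Module):
    """Pixel-shuffle upsampling of the lower level, channel adjustment,
    concatenation with the same-level selected features, then an
    encoder-structure block.  Spatial size doubles relative to the input."""

    def __init__(self, below_channels: int, skip_channels: int,
                 out_channels: int, config: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        if below_channels % 4:
            raise ValueError("lower-level channels must be divisible by 4 for r=2")
        self.adjust = Conv2d(below_channels // 4, out_channels, 3, padding=1,
                             rng=rng, leaky_slope=config.leaky_slope)
        self.block = EncoderBlock(out_channels + skip_channels, out_channels,
                                  config, rng)

    def forward(self, below: Tensor, skip: Tensor) -> Tensor:
        up = ad.pixel_shuffle(below, 2)
        up = self.adjust(up)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"upsampled features {up.shape[2:]} do not match skip {skip.shape[2:]}"
            )
        return self.block(ad.concat([up, skip], axis=1))


class MLPED(Module):
    """Full model: encoder levels joined by average pooling, MLP modules on
    the skip paths, pixel-shuffle decoders, and a linear 1-channel head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channel_schedule
        levels = config.encoder_levels
        self.encoders = [
            EncoderBlock(1 if l == 0 else ch[l - 1], ch[l], config, rng)
            for l in range(levels)
        ]
        self.mlps = [MLPModule(ch[l], config, rng) for l in range(levels - 1)]
        self.decoders = [
            DecoderBlock(ch[l + 1], ch[l], ch[l], config, rng)
            for l in range(levels - 1)
        ]
        self.head = Conv2d(ch[0], 1, 3, padding=1, rng=rng,
                           leaky_slope=config.leaky_slope)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (batch, 1, rows, columns)")
        stride = 2 ** (self.config.encoder_levels - 1)
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(
                f"spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {stride}"
            )
        feats = []
        h = x
        for l, enc in enumerate(self.encoders):
            f = enc(h)
            feats.append(f)
            if l < len(self.encoders) - 1:
                h = ad.avg_pool2d(f, 2)
        skips = [mlp(feats[l]) for l, mlp in enumerate(self.mlps)]
        d = feats[-1]
        for l in range(len(self.decoders) - 1, -1, -1):
            d = self.decoders[l](d, skips[l])
        return self.head(d)


# ---------------------------------------------------------------------------
# spec-surface constructors & serialisation
# ---------------------------------------------------------------------------

def build_encoder_block(in_channels: int, out_channels: int,
                        config: NetworkConfig | None = None,
                        seed: int = 0) -> EncoderBlock:
    config = config or NetworkConfig()
    return EncoderBlock(in_channels, out_channels, config,
                        np.random.default_rng(seed))


def build_decoder_block(below_channels: int, skip_channels: int,
                        out_channels: int,
                        config: NetworkConfig | None = None,
                        seed: int = 0) -> DecoderBlock:
    config = config or NetworkConfig()
    return DecoderBlock(below_channels, skip_channels, out_channels, config,
                        np.random.default_rng(seed))


def build_mlped(config: NetworkConfig | None = None, seed: int = 0) -> MLPED:
    return MLPED(config or NetworkConfig(), seed=seed)


def save_model(model: MLPED, path) -> None:
    """Serialise weights plus the embedded config to a single .npz file."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> MLPED:
    with np.load(path) as archive:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(archive["__config__"]).decode())
        )
        model = MLPED(cfg)
        params = dict(model.named_parameters())
        for name in archive.files:
            if name == "__config__":
                continue
            if name not in params:
                raise ValueError(f"checkpoint parameter {name!r} not in model")
            if params[name].data.shape != archive[name].shape:
                raise ValueError(f"shape mismatch for {name!r}")
            params[name].data = archive[name]
    return model
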