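"""Attention-augmented U-Net for lung-field segmentation.

A four-stage residual encoder (plus stem and bottleneck) and a standard
U-Net decoder with transposed-convolution upsampling. X-attention
blocks can be placed after any encoder stage (position 1 = the
highest-resolution stage); they refine the stage output before it feeds
both the skip connection and the next stage. Y-attention blocks sit on
the decoder: at position i the shallow input is the stage-i skip
feature (already X-refined when X(i) is present, so the two chain) and
the deep input is the decoder feature arriving from the next-deeper
stage. The network ends in a 1x1 convolution and a sigmoid, producing
an H x W probability map the same size as the input.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .attention import XAttention, YAttention, refine
from .autodiff import Tensor
from .errors import ConfigError, PlacementParseError, ShapeError
from .layers import BatchNorm, Conv2d, ConvTranspose2d, Module, ReLU, Sequential

__all__ = [
    "PlacementConfig",
    "NetworkSpec",
    "ENCODER_PRESETS",
    "parse_placement",
    "build_network",
    "predict",
    "AttentionUNet",
    "count_conv3x3",
    "count_learnable_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

ENCODER_PRESETS: dict[str, tuple[tuple[int, int], ...]] = {
    # (channel width, residual blocks) per stage, shallow to deep
    "tiny": ((8, 1), (16, 1), (32, 1), (64, 1)),
    "small": ((16, 2), (32, 2), (64, 2), (128, 2)),
    "resnet101": ((256, 3), (512, 4), (1024, 23), (2048, 3)),
}


@dataclass(frozen=True)
class PlacementConfig:
    """Which encoder/decoder positions (1-4) carry X/Y attention blocks."""

    x_positions: frozenset = frozenset()
    y_positions: frozenset = frozenset()

    def __post_init__(self):
        for s in (self.x_positions, self.y_positions):
            bad = set(s) - {1, 2, 3, 4}
            if bad:
                raise PlacementParseError(f"positions out of range 1-4: {sorted(bad)}")

    @property
    def n_modules(self) -> int:
        return len(self.x_positions) + len(self.y_positions)

    def label(self) -> str:
        toks = [f"X({i})" for i in sorted(self.x_positions)]
        toks += [f"Y({i})" for i in sorted(self.y_positions)]
        return "+".join(toks) if toks else "baseline"


_TOKEN = re.compile(r"^([XY])\((\d+)\)$", re.IGNORECASE)


def parse_placement(label: str) -> PlacementConfig:
    """Parse labels like "X(1)+X(2)+Y(1)+Y(2)" or "baseline".

    Case-insensitive and whitespace-tolerant; unknown tokens or
    positions outside 1-4 raise with the offending token named.
    """
    text = label.strip()
    if text.lower() in ("baseline", ""):
        return PlacementConfig()
    xs: set[int] = set()
    ys: set[int] = set()
    for raw in text.split("+"):
        tok = raw.strip().replace(" ", "")
        m = _TOKEN.match(tok)
        if not m:
            raise PlacementParseError(f"unrecognized placement token {raw.strip()!r}")
        pos = int(m.group(2))
        if pos not in (1, 2, 3, 4):
            raise PlacementParseError(f"position out of range 1-4 in token {raw.strip()!r}")
        (xs if m.group(1).upper() == "X" else ys).add(pos)
    return PlacementConfig(frozenset(xs), frozenset(ys))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description, serializable into checkpoints."""

    encoder_stages: tuple[tuple[int, int], ...] = ENCODER_PRESETS["tiny"]
    input_size: tuple[int, int] = (64, 64)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    reduction_ratio: float = 0.5
    upsample: str = "bilinear"

    def __post_init__(self):
        if len(self.encoder_stages) != 4:
            raise ConfigError("exactly 4 encoder stages are required (positions 1-4)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "encoder_stages": [list(s) for s in self.encoder_stages],
                "input_size": list(self.input_size),
                "x_positions": sorted(self.placement.x_positions),
                "y_positions": sorted(self.placement.y_positions),
                "reduction_ratio": self.reduction_ratio,
                "upsample": self.upsample,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            encoder_stages=tuple(tuple(s) for s in d["encoder_stages"]),
            input_size=tuple(d["input_size"]),
            placement=PlacementConfig(
                frozenset(d["x_positions"]), frozenset(d["y_positions"])
            ),
            reduction_ratio=d["reduction_ratio"],
            upsample=d["upsample"],
        )


class ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1) -> None:
        super().__init__()
        self.conv1 = self.add_module("conv1", Conv2d(in_ch, out_ch, 3, rng, stride=stride))
        self.bn1 = self.add_module("bn1", BatchNorm(out_ch))
        self.conv2 = self.add_module("conv2", Conv2d(out_ch, out_ch, 3, rng))
        self.bn2 = self.add_module("bn2", BatchNorm(out_ch))
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = self.add_module("proj", Conv2d(in_ch, out_ch, 1, rng, stride=stride, pad=0))

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return ad.relu(ad.add(h, skip))


class ResStage(Module):
    """Stride-2 entry block followed by stride-1 residual blocks."""

    def __init__(self, in_ch: int, out_ch: int, n_blocks: int, rng) -> None:
        super().__init__()
        blocks = [ResidualBlock(in_ch, out_ch, rng, stride=2)]
        blocks += [ResidualBlock(out_ch, out_ch, rng) for _ in range(n_blocks - 1)]
        self.body = self.add_module("body", Sequential(*blocks))

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng) -> None:
        super().__init__()
        self.body = self.add_module(
            "body",
            Sequential(
                Conv2d(in_ch, out_ch, 3, rng), BatchNorm(out_ch), ReLU(),
                Conv2d(out_ch, out_ch, 3, rng), BatchNorm(out_ch), ReLU(),
            ),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class AttentionUNet(Module):
    """The full encoder-decoder with configurable attention placement."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [w for w, _ in spec.encoder_stages]
        blocks = [b for _, b in spec.encoder_stages]
        w0 = widths[0]

        self.stem = self.add_module(
            "stem", Sequential(Conv2d(1, w0, 3, rng), BatchNorm(w0), ReLU())
        )
        prev = w0
        for i, (w, nb) in enumerate(zip(widths, blocks), start=1):
            self.add_module(f"enc{i}", ResStage(prev, w, nb, rng))
            prev = w
        w_bott = 2 * widths[3]
        self.add_module("bottleneck", ResStage(widths[3], w_bott, 1, rng))

        for i in sorted(spec.placement.x_positions):
            self.add_module(
                f"xatt{i}",
                XAttention(widths[i - 1], spec.reduction_ratio, rng, spec.upsample),
            )
        deep_ch = {4: w_bott, 3: widths[3], 2: widths[2], 1: widths[1]}
        for i in sorted(spec.placement.y_positions):
            self.add_module(
                f"yatt{i}",
                YAttention(widths[i - 1], deep_ch[i], spec.reduction_ratio, rng, spec.upsample),
            )

        prev = w_bott
        for i in (4, 3, 2, 1):
            w = widths[i - 1]
            self.add_module(f"up{i}", ConvTranspose2d(prev, w, rng))
            self.add_module(f"dec{i}", DoubleConv(2 * w, w, rng))
            prev = w
        self.add_module("up0", ConvTranspose2d(widths[0], w0, rng))
        self.add_module("dec0", DoubleConv(2 * w0, w0, rng))
        self.head = self.add_module("head", Conv2d(w0, 1, 1, rng, pad=0))
        # per-placement on/off switches, useful for ablation probes
        self.enabled = {("x", i): True for i in spec.placement.x_positions}
        self.enabled.update({("y", i): True for i in spec.placement.y_positions})

    def forward(self, x: Tensor, probe: dict | None = None) -> Tensor:
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ShapeError(f"input size must be divisible by 32, got {h}x{w}")
        feats = {}
        s0 = self.stem(x)
        d = s0
        for i in (1, 2, 3, 4):
            d = self._modules[f"enc{i}"](d)
            if i in self.spec.placement.x_positions and self.enabled[("x", i)]:
                d = self._modules[f"xatt{i}"](d)
            feats[i] = d
            if probe is not None:
                probe[f"skip{i}"] = d.data.copy()
        d = self._modules["bottleneck"](feats[4])
        for i in (4, 3, 2, 1):
            skip = feats[i]
            if i in self.spec.placement.y_positions and self.enabled[("y", i)]:
                if probe is not None:
                    probe[f"y_in{i}"] = skip.data.copy()
                skip = self._modules[f"yatt{i}"](skip, d)
            u = self._modules[f"up{i}"](d)
            d = self._modules[f"dec{i}"](ad.concat(u, skip))
        u = self._modules["up0"](d)
        d = self._modules["dec0"](ad.concat(u, s0))
        return ad.sigmoid(self.head(d))


def build_network(spec: NetworkSpec, seed: int = 0) -> AttentionUNet:
    """Seeded construction of the attention-augmented U-Net."""
    return AttentionUNet(spec, seed)


def predict(net: AttentionUNet, image: np.ndarray) -> np.ndarray:
    """Probability map for one preprocessed H x W image.

    Integer images are rescaled from [0, 255] to [0, 1]. The network is
    evaluated in inference mode, so the output is deterministic for
    fixed weights.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ShapeError(f"expected an H x W image, got shape {image.shape}")
    if image.shape != tuple(net.spec.input_size):
        raise ShapeError(
            f"image size {image.shape} does not match network input {net.spec.input_size}"
        )
    x = image.astype(np.float64)
    if np.issubdtype(image.dtype, np.integer):
        x = x / 255.0
    was_training = net.training
    net.eval()
    out = net(Tensor(x[None, None])).data[0, 0]
    if was_training:
        net.train()
    return out


def count_conv3x3(module: Module) -> int:
    """Number of learnable 3x3 convolution layers inside a module."""
    return sum(1 for m in module.modules() if isinstance(m, Conv2d) and m.kernel == 3)


def count_learnable_parameters(spec: NetworkSpec) -> int:
    """Learnable-parameter count of ``spec`` without instantiating it.

    Mirrors the module construction arithmetic exactly (verified against
    ``AttentionUNet.n_parameters()`` in the test suite); useful for
    full-scale encoder presets whose weights would not fit in memory.
    """
    from .attention import hidden_width

    def conv(cin, cout, k, bias=True):
        return cin * cout * k * k + (cout if bias else 0)

    def bn(c):
        return 2 * c

    def res_block(cin, cout, stride):
        n = conv(cin, cout, 3) + bn(cout) + conv(cout, cout, 3) + bn(cout)
        if stride != 1 or cin != cout:
            n += conv(cin, cout, 1)
        return n

    def res_stage(cin, cout, nb):
        return res_block(cin, cout, 2) + (nb - 1) * res_block(cout, cout, 1)

    def double_conv(cin, cout):
        return conv(cin, cout, 3) + bn(cout) + conv(cout, cout, 3) + bn(cout)

    def channel_att(cin, cout, r):
        h = hidden_width(cin, r)
        return (cin * h + h) + (h * cout) + bn(cout)  # fc0 + fc1 (no bias) + bn

    def spatial_att(c):
        return 5 * conv(c, c, 3)

    widths = [w for w, _ in spec.encoder_stages]
    blocks = [b for _, b in spec.encoder_stages]
    w0, w_bott = widths[0], 2 * widths[3]
    r = spec.reduction_ratio
    total = conv(1, w0, 3) + bn(w0)  # stem
    prev = w0
    for w, nb in zip(widths, blocks):
        total += res_stage(prev, w, nb)
        prev = w
    total += res_stage(widths[3], w_bott, 1)  # bottleneck
    for i in spec.placement.x_positions:
        c = widths[i - 1]
        total += channel_att(c, c, r) + spatial_att(c)
    deep_ch = {4: w_bott, 3: widths[3], 2: widths[2], 1: widths[1]}
    for i in spec.placement.y_positions:
        c = widths[i - 1]
        total += channel_att(deep_ch[i], c, r) + spatial_att(c)
    prev = w_bott
    for i in (4, 3, 2, 1):
        w = widths[i - 1]
        total += prev * w * 4 + w          # up-convolution
        total += double_conv(2 * w, w)
        prev = w
    total += widths[0] * w0 * 4 + w0       # up0
    total += double_conv(2 * w0, w0)
    total += conv(w0, 1, 1)                # head
    return total


def save_checkpoint(path, net: AttentionUNet) -> None:
    """Single-file checkpoint: JSON architecture header plus weight arrays."""
    state = net.state_dict()
    np.savez(path, __spec__=np.frombuffer(net.spec.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> AttentionUNet:
    from pathlib import Path

    p = Path(path)
    if not p.exists() and p.suffix != ".npz":
        p = Path(str(p) + ".npz")
    with np.load(p) as z:
        spec = NetworkSpec.from_json(bytes(z["__spec__"]).decode())
        net = build_network(spec, seed=0)
        state = {k: z[k] for k in z.files if k != "__spec__"}
    net.load_state_dict(state)
    return net
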