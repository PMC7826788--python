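"""Channel, pyramid-spatial, X- and Y-attention blocks with residual refinement.

The X-attention block answers *what* and *where* to attend to for a
single feature map: a squeeze-and-excitation style channel branch
(global average pooling followed by a one-hidden-layer MLP, batch norm
and ReLU) produces a per-channel weight vector, a three-scale
convolutional pyramid produces a per-position map, and their broadcast
product is squashed through a sigmoid into an attention map in (0, 1).
The Y-attention block is the two-input variant: the channel branch reads
a *deeper* feature map (global context) while the spatial branch reads
the shallower one (local detail); the MLP also adapts the deeper map's
channel count to the shallower one's. Both refine features residually,

    F_out = M (*) F_in + F_in,

so the identity path is never destroyed and, for non-negative input,
the refined features stay within [F_in, 2 F_in].

Two surfaces are provided: differentiable :class:`Module` blocks used
inside the segmentation network, and a functional numpy API
(:func:`channel_attention` etc.) driven by explicit parameter records,
convenient for tests and for evaluating the blocks in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DimensionError, ShapeError, ValidationError
from .layers import BatchNorm, Conv2d, Linear, Module

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "ChannelAttention",
    "SpatialAttention",
    "XAttention",
    "YAttention",
    "channel_attention",
    "spatial_attention",
    "x_attention_map",
    "y_attention_map",
    "residual_refine",
    "hidden_width",
]


def hidden_width(c_in: int, r: float) -> int:
    """MLP hidden width: max(1, round(r * C_in)) for reduction ratio r in (0, 1]."""
    if not (0.0 < r <= 1.0):
        raise ValidationError(f"reduction ratio must be in (0, 1], got {r}")
    return max(1, int(round(r * c_in)))


def _check_feature_map(f: np.ndarray, name: str = "feature map") -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise DimensionError(f"{name} must be C x H x W, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValidationError(f"{name} contains non-finite values")
    return f


# ---------------------------------------------------------------------------
# parameter records (functional surface)


@dataclass
class ChannelAttentionParams:
    """Weights of the channel-attention branch.

    ``w0`` maps C_in -> hidden, ``w1`` maps hidden -> C_out; batch-norm
    scale/shift and running statistics act on the C_out output. The
    hidden width obeys ``max(1, round(r * C_in))``.
    """

    w0: np.ndarray
    w1: np.ndarray
    b0: np.ndarray | None = None
    b1: np.ndarray | None = None
    bn_gamma: np.ndarray | None = None
    bn_beta: np.ndarray | None = None
    bn_mean: np.ndarray | None = None
    bn_var: np.ndarray | None = None
    reduction_ratio: float = 0.5
    hidden_activation: str = "relu"
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        self.w0 = np.atleast_2d(np.asarray(self.w0, dtype=np.float64))
        self.w1 = np.atleast_2d(np.asarray(self.w1, dtype=np.float64))
        hidden, c_in = self.w0.shape
        c_out, hidden2 = self.w1.shape
        if hidden != hidden2:
            raise DimensionError(
                f"w0 hidden width {hidden} does not match w1 hidden width {hidden2}"
            )
        if hidden != hidden_width(c_in, self.reduction_ratio):
            raise ValidationError(
                f"hidden width {hidden} inconsistent with r={self.reduction_ratio}, C_in={c_in}"
            )
        if self.b0 is None:
            self.b0 = np.zeros(hidden)
        if self.b1 is None:
            self.b1 = np.zeros(c_out)
        if self.bn_gamma is None:
            self.bn_gamma = np.ones(c_out)
        if self.bn_beta is None:
            self.bn_beta = np.zeros(c_out)
        if self.bn_mean is None:
            self.bn_mean = np.zeros(c_out)
        if self.bn_var is None:
            self.bn_var = np.ones(c_out)
        for name in ("w0", "w1", "b0", "b1", "bn_gamma", "bn_beta", "bn_mean", "bn_var"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")
        if self.hidden_activation not in ("relu", "identity"):
            raise ValidationError(f"unknown hidden activation {self.hidden_activation!r}")

    @property
    def c_in(self) -> int:
        return self.w0.shape[1]

    @property
    def c_out(self) -> int:
        return self.w1.shape[0]


@dataclass
class SpatialAttentionParams:
    """The five 3x3 convolution kernels of the spatial pyramid.

    Two stride-2 layers on the contracting side, one at the coarsest
    scale and two on the expanding side; all map C -> C channels.
    """

    down1_w: np.ndarray
    down2_w: np.ndarray
    coarse_w: np.ndarray
    up2_w: np.ndarray
    up1_w: np.ndarray
    down1_b: np.ndarray | None = None
    down2_b: np.ndarray | None = None
    coarse_b: np.ndarray | None = None
    up2_b: np.ndarray | None = None
    up1_b: np.ndarray | None = None
    upsample: str = "bilinear"

    _KERNELS = ("down1", "down2", "coarse", "up2", "up1")

    def __post_init__(self) -> None:
        c = None
        for name in self._KERNELS:
            w = np.asarray(getattr(self, name + "_w"), dtype=np.float64)
            if w.ndim != 4 or w.shape[2:] != (3, 3):
                raise DimensionError(f"{name}_w must be C x C x 3 x 3, got {w.shape}")
            if w.shape[0] != w.shape[1]:
                raise DimensionError(f"{name}_w must preserve the channel count")
            if c is None:
                c = w.shape[0]
            elif w.shape[0] != c:
                raise DimensionError("all pyramid kernels must share one channel count")
            if not np.all(np.isfinite(w)):
                raise ValidationError(f"non-finite values in {name}_w")
            setattr(self, name + "_w", w)
            b = getattr(self, name + "_b")
            b = np.zeros(c) if b is None else np.asarray(b, dtype=np.float64)
            if b.shape != (c,) or not np.all(np.isfinite(b)):
                raise ValidationError(f"invalid bias for {name}")
            setattr(self, name + "_b", b)
        self.channels = c
        if self.upsample not in ("bilinear", "nearest"):
            raise ValidationError(f"unknown upsample mode {self.upsample!r}")


# ---------------------------------------------------------------------------
# differentiable modules


class ChannelAttention(Module):
    """GAP -> MLP -> BN -> ReLU, yielding one non-negative weight per channel.

    With ``c_out != c_in`` the MLP also adapts the channel count, as the
    Y-attention block requires when the deep feature map is wider than
    the shallow one.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int | None = None,
        r: float = 0.5,
        rng: np.random.Generator | None = None,
        hidden_activation: str = "relu",
    ) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c_out = c_in if c_out is None else c_out
        self.c_in, self.c_out, self.r = c_in, c_out, r
        self.hidden_activation = hidden_activation
        hidden = hidden_width(c_in, r)
        self.fc0 = self.add_module("fc0", Linear(c_in, hidden, rng))
        # small positive bias keeps the hidden ReLU units alive at
        # initialization (an all-dead hidden layer would gate the whole
        # block off and freeze its gradients)
        self.fc0.b.data[...] = 0.1
        # no bias on the layer feeding batch norm: the normalization would
        # cancel it under batch statistics, leaving a dead parameter
        self.fc1 = self.add_module("fc1", Linear(hidden, c_out, rng, bias=False))
        self.bn = self.add_module("bn", BatchNorm(c_out))

    def forward(self, x: Tensor) -> Tensor:
        """(N, C_in, H, W) -> (N, C_out) non-negative channel weights."""
        g = ad.global_avg_pool(x)
        h = self.fc0(g)
        if self.hidden_activation == "relu":
            h = ad.relu(h)
        return ad.relu(self.bn(self.fc1(h)))

    @classmethod
    def from_params(cls, p: ChannelAttentionParams) -> "ChannelAttention":
        m = cls(p.c_in, p.c_out, r=p.reduction_ratio, hidden_activation=p.hidden_activation)
        m.fc0.w.data[...] = p.w0
        m.fc0.b.data[...] = p.b0
        m.fc1.w.data[...] = p.w1
        m.bn.gamma.data[...] = p.bn_gamma
        m.bn.beta.data[...] = p.bn_beta
        # the MLP output bias commutes with BN under running statistics:
        # BN(x + b1) = BN'(x) with the running mean shifted by -b1
        m.bn.running_mean[...] = np.asarray(p.bn_mean) - np.asarray(p.b1)
        m.bn.running_var[...] = p.bn_var
        m.bn.eps = p.bn_eps
        return m


class SpatialAttention(Module):
    """Three-scale convolutional pyramid producing a per-position map.

    The input is contracted twice by stride-2 3x3 convolutions (H ->
    H/2 -> H/4), passed through one coarsest-scale convolution, then
    expanded back with lateral additions in feature-pyramid style; the
    up-sampled expanding output is finally added to the input map, so
    with all-zero kernels the block is the identity. Exactly five
    learnable 3x3 convolution layers; the x2 up-sampling operator is a
    fixed (parameter-free) bilinear or nearest interpolation.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator | None = None,
        upsample: str = "bilinear",
    ) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.upsample = upsample
        self.down1 = self.add_module("down1", Conv2d(channels, channels, 3, rng, stride=2))
        self.down2 = self.add_module("down2", Conv2d(channels, channels, 3, rng, stride=2))
        self.coarse = self.add_module("coarse", Conv2d(channels, channels, 3, rng))
        self.up2 = self.add_module("up2", Conv2d(channels, channels, 3, rng))
        self.up1 = self.add_module("up1", Conv2d(channels, channels, 3, rng))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h % 4 or w % 4:
            raise ShapeError(f"spatial attention needs H, W divisible by 4, got {h}x{w}")
        c1 = self.down1(x)                                   # H/2
        c2 = self.down2(c1)                                  # H/4
        b = self.coarse(c2)                                  # H/4
        e2 = self.up2(ad.add(ad.upsample2x(b, self.upsample), c1))  # H/2
        e1 = ad.upsample2x(self.up1(e2), self.upsample)      # H
        return ad.add(e1, x)

    @classmethod
    def from_params(cls, p: SpatialAttentionParams) -> "SpatialAttention":
        m = cls(p.channels, upsample=p.upsample)
        for name in SpatialAttentionParams._KERNELS:
            conv = getattr(m, name)
            conv.w.data[...] = getattr(p, name + "_w")
            conv.b.data[...] = getattr(p, name + "_b")
        return m


def _fuse(spatial: Tensor, channel: Tensor) -> Tensor:
    """sigma(F_spatial (*) F_channel) with per-channel broadcasting."""
    n, c = channel.shape
    cv = ad.reshape(channel, (n, c, 1, 1))
    return ad.sigmoid(ad.mul(spatial, cv))


def refine(f: Tensor, m: Tensor) -> Tensor:
    """Residual refinement F_out = M (*) F + F on tensors."""
    return ad.add(ad.mul(m, f), f)


class XAttention(Module):
    """Single-input attention block: both branches read the same map."""

    def __init__(self, channels: int, r: float = 0.5, rng: np.random.Generator | None = None,
                 upsample: str = "bilinear") -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.channel = self.add_module("channel", ChannelAttention(channels, channels, r, rng))
        self.spatial = self.add_module("spatial", SpatialAttention(channels, rng, upsample))

    def attention_map(self, f: Tensor) -> Tensor:
        return _fuse(self.spatial(f), self.channel(f))

    def forward(self, f: Tensor) -> Tensor:
        return refine(f, self.attention_map(f))


class YAttention(Module):
    """Two-input attention block: channel branch reads the deeper map.

    ``deep_channels`` may differ from ``channels``; the channel-branch
    MLP adapts the width so the broadcast product is defined.
    """

    def __init__(self, channels: int, deep_channels: int, r: float = 0.5,
                 rng: np.random.Generator | None = None, upsample: str = "bilinear") -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels, self.deep_channels = channels, deep_channels
        self.channel = self.add_module("channel", ChannelAttention(deep_channels, channels, r, rng))
        self.spatial = self.add_module("spatial", SpatialAttention(channels, rng, upsample))

    def attention_map(self, f: Tensor, f_deep: Tensor) -> Tensor:
        return _fuse(self.spatial(f), self.channel(f_deep))

    def forward(self, f: Tensor, f_deep: Tensor) -> Tensor:
        return refine(f, self.attention_map(f, f_deep))


# ---------------------------------------------------------------------------
# functional numpy surface


def channel_attention(f: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Per-channel attention weights for a C x H x W feature map.

    Returns a C_out x 1 x 1 non-negative array; invariant under any
    permutation of the spatial positions of ``f`` (the first step is a
    global average pool).
    """
    f = _check_feature_map(f)
    if f.shape[0] != params.c_in:
        raise DimensionError(
            f"feature map has {f.shape[0]} channels, params expect {params.c_in}"
        )
    mod = ChannelAttention.from_params(params).eval()
    out = mod(Tensor(f[None]))
    return out.data[0].reshape(params.c_out, 1, 1)


def spatial_attention(f: np.ndarray, params: SpatialAttentionParams) -> np.ndarray:
    """Pyramid spatial attention: C x H x W in, C x H x W out."""
    f = _check_feature_map(f)
    if f.shape[0] != params.channels:
        raise DimensionError(
            f"feature map has {f.shape[0]} channels, params expect {params.channels}"
        )
    mod = SpatialAttention.from_params(params).eval()
    return mod(Tensor(f[None])).data[0]


def x_attention_map(
    f: np.ndarray, cp: ChannelAttentionParams, sp: SpatialAttentionParams
) -> np.ndarray:
    """M_X = sigma(F_spatial (*) F_channel); entries strictly in (0, 1)."""
    f = _check_feature_map(f)
    if cp.c_in != cp.c_out or cp.c_in != f.shape[0]:
        raise DimensionError(
            "X-attention channel branch must map C -> C for the input's channel count"
        )
    fs = spatial_attention(f, sp)
    fc = channel_attention(f, cp)
    from scipy.special import expit

    return expit(fs * fc)


def y_attention_map(
    f: np.ndarray,
    f_deep: np.ndarray,
    cp: ChannelAttentionParams,
    sp: SpatialAttentionParams,
) -> np.ndarray:
    """M_Y = sigma(F_spatial(f) (*) F'_channel(f_deep)); shape follows ``f``."""
    f = _check_feature_map(f)
    f_deep = _check_feature_map(f_deep, "deep feature map")
    if cp.c_in != f_deep.shape[0]:
        raise DimensionError(
            f"channel branch expects {cp.c_in} input channels, deep map has {f_deep.shape[0]}"
        )
    if cp.c_out != f.shape[0]:
        raise DimensionError(
            f"channel branch outputs {cp.c_out} channels but the shallow map has {f.shape[0]}"
        )
    fs = spatial_attention(f, sp)
    fc = channel_attention(f_deep, cp)
    from scipy.special import expit

    return expit(fs * fc)


def residual_refine(f: np.ndarray, m: np.ndarray) -> np.ndarray:
    """F_out = M (*) F + F elementwise; shapes must match exactly."""
    f = _check_feature_map(f)
    m = np.asarray(m, dtype=np.float64)
    if m.shape != f.shape:
        raise DimensionError(f"attention map shape {m.shape} != feature shape {f.shape}")
    if not np.all(np.isfinite(m)):
        raise ValidationError("attention map contains non-finite values")
    return m * f + f
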