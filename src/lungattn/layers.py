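"""Layer abstractions over the autodiff engine.

A light module system in the spirit of the mainstream deep-learning
frameworks: a :class:`Module` owns named parameters, buffers and
submodules, exposes a flat ``state_dict`` and a train/eval mode switch.
Kernels use fan-in-scaled uniform initialization from a caller-provided
random generator; biases start at zero.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters, buffers and submodules by name."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # -- registration ------------------------------------------------------
    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._buffers[name] = arr
        return arr

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    # -- traversal ---------------------------------------------------------
    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield prefix + k, v
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode --------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data.copy()
        for k, v in self._buffers.items():
            out[prefix + k] = v.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            src = state[prefix + k]
            if src.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}")
            v.data[...] = src
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.w = self.register_parameter(
            "w", _fan_in_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        )
        self.b = self.register_parameter("b", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 transposed convolution (exact x2 up-convolution)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = self.register_parameter("w", _fan_in_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.b = self.register_parameter("b", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalization for (N, C) or (N, C, H, W) inputs.

    Falls back to the running statistics whenever the batch provides a
    single element per channel, so training at batch size 1 is defined.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register_parameter("gamma", np.ones(n_features))
        self.beta = self.register_parameter("beta", np.zeros(n_features))
        self.running_mean = self.register_buffer("running_mean", np.zeros(n_features))
        self.running_var = self.register_buffer("running_var", np.ones(n_features))

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        self.w = self.register_parameter("w", _fan_in_uniform(rng, (out_f, in_f), in_f))
        self.b = self.register_parameter("b", np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)


class Sequential(Module):
    def __init__(self, *mods: Module) -> None:
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self.add_module(str(i), m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.sigmoid(x)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
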