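"""Layer/module abstractions over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from .conv import conv3d, conv_transpose3d, instance_norm
from .tensor import Tensor

__all__ = ["Module", "Conv3d", "ConvTranspose3d", "InstanceNorm3d", "Sequential"]


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution with He-uniform initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, pad: int | None = None, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_channels * kernel ** 3
        bound = float(np.sqrt(6.0 / fan_in))
        shape = (out_channels, in_channels, kernel, kernel, kernel)
        if zero_init:
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = rng.uniform(-bound, bound, size=shape).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose3d(Module):
    """Block-upsampling transposed convolution (kernel size == stride)."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        fan_in = in_channels * stride ** 3
        bound = float(np.sqrt(6.0 / fan_in))
        w = rng.uniform(-bound, bound,
                        size=(in_channels, out_channels, stride, stride, stride))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, eps=self.eps)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
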