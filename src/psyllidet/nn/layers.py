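"""Layer and optimiser primitives on top of the autograd engine."""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Conv2d", "Linear", "ReLU", "Sequential", "SGD"]


class Module:
    """Base class: tracks parameters and submodules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_modules(self, prefix: str = "") -> Iterable:
        yield prefix, self
        for name, m in self._modules.items():
            yield from m.named_modules(f"{prefix}.{name}" if prefix else name)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        flat = {}
        for name, m in self.named_modules():
            for pname, p in m._params.items():
                flat[f"{name}.{pname}" if name else pname] = p.data.copy()
        return flat

    def load_state_dict(self, state: dict) -> None:
        for name, m in self.named_modules():
            for pname, p in m._params.items():
                key = f"{name}.{pname}" if name else pname
                p.data[...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels, k, k), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(
            _kaiming(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class SGD:
    """Plain SGD with momentum and optional gradient clipping."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.01, momentum: float = 0.9,
                 clip: Optional[float] = 10.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.clip = clip
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.clip is not None:
                norm = np.linalg.norm(g)
                if norm > self.clip:
                    g = g * (self.clip / norm)
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
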