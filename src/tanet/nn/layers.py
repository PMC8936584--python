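"""Layer modules on top of the autodiff engine.

Parameters are ``Tensor``s with ``requires_grad=True``; frozen state (batch
norm running statistics, fixed anchor filters) lives in buffers so it is
serialized with the model but never touched by the optimizer.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "ModuleList", "Sequential", "Conv2d", "DepthwiseConv2d",
           "BatchNorm2d", "Linear", "Identity"]


class Module:
    def __init__(self):
        self.training = True
        self._buffer_names: set[str] = set()

    # -- registration --------------------------------------------------------
    def register_buffer(self, name: str, value):
        setattr(self, name, value)
        self._buffer_names.add(name)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad and name not in self._buffer_names:
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_state(self, prefix: str = ""):
        """Parameters and buffers, for (de)serialization."""
        for name, v in vars(self).items():
            if isinstance(v, Tensor):
                yield prefix + name, v
            elif name in self._buffer_names and isinstance(v, np.ndarray):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_state(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: (v.data if isinstance(v, Tensor) else v).copy()
                for k, v in self.named_state()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, v in own.items():
            src = np.asarray(state[k])
            if isinstance(v, Tensor):
                if v.data.shape != src.shape:
                    raise ValueError(f"shape mismatch for {k}")
                v.data = src.astype(v.data.dtype, copy=True)
            else:
                v[...] = src

    # -- mode ----------------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = ModuleList(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = Tensor(_he_init(rng, (c_out, c_in, k, k), c_in * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2
        self.weight = Tensor(_he_init(rng, (c, k, k), k * k), requires_grad=True)

    def forward(self, x):
        return T.depthwise_conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float64))
        self.register_buffer("running_var", np.ones(c, dtype=np.float64))

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (f_in, f_out), f_in), requires_grad=True)
        self.bias = Tensor(np.zeros(f_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)
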