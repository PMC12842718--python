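"""Layers and module container for the numpy autograd engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, maxpool2d

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
           "Sequential"]


class Module:
    """Base class: tracks parameters/submodules by attribute, torch-style."""

    def __init__(self):
        self._parameters: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        params = list(self._parameters.values())
        for m in self._modules.values():
            params.extend(m.parameters())
        return params

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: p.data.copy() for k, p in self._parameters.items()}
        for k, v in self._buffers.items():
            state[prefix + k] = np.asarray(getattr(self, k)).copy()
        for name, m in self._modules.items():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._parameters.items():
            p.data = np.array(state[prefix + k], dtype=p.dtype)
        for k in list(self._buffers.keys()):
            arr = np.array(state[prefix + k])
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (in_features, out_features),
                                      in_features, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels, kernel_size, kernel_size),
                     fan_in, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(num_features, dtype=dtype))
        self.register_buffer("running_var", np.ones(num_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import batchnorm2d
        shape = (1, -1, 1, 1)
        if self.training:
            out, mean, var = batchnorm2d(x, self.gamma, self.beta, self.eps)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm = ((1 - self.momentum) * rm + self.momentum * mean).astype(rm.dtype)
            rv = ((1 - self.momentum) * rv + self.momentum * var).astype(rv.dtype)
            self.register_buffer("running_mean", rm)
            self.register_buffer("running_var", rv)
            return out
        mean = Tensor(self._buffers["running_mean"].reshape(shape))
        var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.k)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
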