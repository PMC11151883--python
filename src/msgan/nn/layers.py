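"""Layer modules built on the autodiff tensor primitives."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

INIT_SD = 0.02  # zero-mean Gaussian weight init, DCGAN/pix2pix convention


class Module:
    """Base class: parameter registration, train/eval mode, recursion."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride, padding,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        w = rng.normal(0.0, INIT_SD, size=(out_channels, in_channels * kernel * kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.kernel, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride, padding,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        w = rng.normal(0.0, INIT_SD, size=(in_channels, out_channels * kernel * kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x):
        return T.conv_transpose2d(x, self.weight, self.bias, self.kernel, self.stride,
                                  self.padding)


class InstanceNorm2d(Module):
    def __init__(self, channels, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x):
        return T.instance_norm(x, self.gamma, self.beta, self.eps)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return T.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Tanh(Module):
    def forward(self, x):
        return T.tanh(x)


class Dropout(Module):
    """Seeded inverted dropout; the mask stream advances only in training mode."""

    def __init__(self, rate: float, seed: int):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return T.dropout(x, self.rate, self.rng, training=self.training)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
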