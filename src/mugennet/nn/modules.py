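"""Neural-network building blocks on top of the autodiff tensor.

Modules follow the familiar container pattern: parameters and submodules are
registered via attribute assignment, ``state_dict`` flattens them for
checkpointing, and ``train``/``eval`` toggles batch-norm statistics.  All
weight initialisation draws from an explicit ``numpy.random.Generator`` so a
model build is reproducible from a single seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, conv2d, max_pool2x2

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ----------------------------------------------------
    def state_dict(self, prefix: str = "", out: OrderedDict | None = None) -> OrderedDict:
        if out is None:
            out = OrderedDict()
        for name, p in self._parameters.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for mname, m in self._modules.items():
            m.state_dict(prefix + mname + ".", out)
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._parameters.items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter in checkpoint: {key}")
            if state[key].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}: {state[key].shape} vs {p.data.shape}")
            p.data = state[key].astype(p.data.dtype, copy=True)
        for name in self._buffers:
            key = prefix + name
            if key in state:
                self._set_buffer(name, state[key].copy())
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        dtype = dtype or DEFAULT_DTYPE
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True, dtype=None):
        super().__init__()
        dtype = dtype or DEFAULT_DTYPE
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.weight = Parameter((rng.standard_normal((c_out, c_in, kernel, kernel)) * std).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, dtype=None, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        dtype = dtype or DEFAULT_DTYPE
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(c, dtype=dtype))
        self.register_buffer("running_var", np.ones(c, dtype=dtype))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * mu.data.reshape(c)).astype(self.running_mean.dtype))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * var.data.reshape(c)).astype(self.running_var.dtype))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalisation over the last dimension (token embeddings)."""

    def __init__(self, dim: int, dtype=None, eps: float = 1e-5):
        super().__init__()
        dtype = dtype or DEFAULT_DTYPE
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return max_pool2x2(x)


class Adam:
    """Adaptive-moment gradient descent (the optimiser of the training protocol)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
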