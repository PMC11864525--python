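"""Layer abstractions (Conv3d, BatchNorm3d, activations, Sequential)."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor
from . import functional as F

__all__ = [
    "Parameter", "Module", "Conv3d", "ReLU", "PReLU", "Identity",
    "MaxPool3d", "BatchNorm3d", "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter traversal, train/eval mode, state export."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        """Exclude every parameter from optimization (loss networks)."""
        for p in self.parameters():
            p.requires_grad = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        self._collect_buffers("", state)
        return state

    def _collect_buffers(self, prefix: str, state: dict) -> None:
        for k, v in self._buffers().items():
            state[prefix + k] = v.copy()
        for cname, child in self.children():
            child._collect_buffers(prefix + cname + ".", state)

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, arr in state.items():
            if name in own:
                own[name].data = np.asarray(arr, dtype=np.float32).reshape(own[name].shape)
            else:
                self._load_buffer(name, arr)

    def _load_buffer(self, name: str, arr: np.ndarray) -> None:
        parts = name.split(".")
        obj = self
        for part in parts[:-1]:
            if isinstance(obj, (list, tuple)):
                obj = obj[int(part)]
            elif part.isdigit() and hasattr(obj, "layers"):
                obj = obj.layers[int(part)]
            else:
                obj = getattr(obj, part)
        setattr(obj, parts[-1], np.asarray(arr, dtype=np.float32))


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding="same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        k = kernel_size if isinstance(kernel_size, (tuple, list)) else (kernel_size,) * 3
        self.kernel_size = tuple(int(v) for v in k)
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel_size))
        bound = 1.0 / math.sqrt(fan_in)  # torch-style default, overwritten by init schemes
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            size=(out_channels, in_channels) + self.kernel_size))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_channels,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class PReLU(Module):
    """Parametric ReLU with a single learnable negative slope (init 0.25)."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.full((1,), init))

    def forward(self, x: Tensor) -> Tensor:
        pos = x.relu()
        return pos + self.alpha * (x - pos)


class MaxPool3d(Module):
    def __init__(self, kernel_size=2, stride=None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool3d(x, self.kernel_size, self.stride)


class BatchNorm3d(Module):
    """Per-channel batch normalization over (B, D, H, W).

    Training mode normalizes with batch statistics and updates running
    averages; eval mode uses the running averages.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, self.num_features, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            n = x.data.size / self.num_features
            with np.errstate(all="ignore"):
                self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
                unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
                self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        for i, layer in enumerate(self.layers):
            yield str(i), layer

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
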