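"""Layer primitives built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import ops

__all__ = [
    "Module", "ModuleList", "Parameter", "Conv3d", "ConvTranspose3d",
    "Linear", "GroupNorm", "LayerNorm", "PReLU", "LeakyReLU",
    "ConvGNPReLU", "SqueezeExcite",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, mode flag, state dict."""

    def __init__(self):
        self.training = True

    # parameters ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield path, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(prefix=path + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # modes ---------------------------------------------------------------
    def modules(self):
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    # serialization --------------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            p.data = np.asarray(state[name]).reshape(p.data.shape).astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution with odd kernel sizes."""

    def __init__(self, c_in, c_out, kernel, rng, bias=True, dtype=np.float32):
        super().__init__()
        kernel = tuple(kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.weight = Parameter(_he_init(rng, (c_out, c_in) + kernel, fan_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x):
        return ops.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Transpose convolution with kernel == stride (learned upsampling)."""

    def __init__(self, c_in, c_out, stride, rng, bias=True, dtype=np.float32):
        super().__init__()
        self.stride = tuple(stride)
        self.weight = Parameter(_he_init(rng, (c_in, c_out) + self.stride, c_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x):
        return ops.conv_transpose3d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, d_in, d_out, rng, bias=True, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (d_in, d_out), d_in, dtype))
        self.bias = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Group normalization over (N, C, D, H, W); statistics per (sample, group)."""

    def __init__(self, channels, groups=8, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x):
        n, c, d, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * d * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) * (var + self.eps) ** -0.5
        xn = xn.reshape(n, c, d, h, w)
        gamma = self.gamma.reshape(1, c, 1, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1, 1)
        return xn * gamma + beta


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class PReLU(Module):
    def __init__(self, channels, init=0.25, dtype=np.float32):
        super().__init__()
        self.alpha = Parameter(np.full(channels, init, dtype=dtype))

    def forward(self, x):
        a = self.alpha.reshape((1, -1) + (1,) * (x.ndim - 2))
        return x.relu() + a * x.neg_part()


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.relu() + self.slope * x.neg_part()


class ConvGNPReLU(Module):
    """Conv -> GroupNorm -> PReLU, the basic block of the As-encoder/decoder."""

    def __init__(self, c_in, c_out, kernel, rng, groups=8, dtype=np.float32):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, kernel, rng, dtype=dtype)
        self.norm = GroupNorm(c_out, groups, dtype=dtype)
        self.act = PReLU(c_out, dtype=dtype)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class SqueezeExcite(Module):
    """Channel gating: global average pool -> bottleneck MLP -> sigmoid."""

    def __init__(self, channels, reduction, rng, dtype=np.float32):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype=dtype)

    def gate(self, x):
        s = x.mean(axis=(2, 3, 4))  # N,C
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x):
        g = self.gate(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1, 1)
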