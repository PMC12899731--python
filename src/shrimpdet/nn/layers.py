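"""Neural-network layers built on the autograd core.

Includes the basic blocks a modern one-stage detector needs: convolution,
batch normalization (with running statistics and fold-into-conv support),
SiLU activation, pooling, and a ``Module`` container with parameter
registration, train/eval modes and an Adam optimizer.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base container: child modules and parameters are discovered by attribute."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for name, value in vars(m).items():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state dict ----------------------------------------------------
    def state_dict(self, prefix: str = "", out=None):
        if out is None:
            out = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, np.ndarray):
                out[key] = value
            elif isinstance(value, Module):
                value.state_dict(prefix=key + ".", out=out)
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v.state_dict(prefix=f"{key}.{i}.", out=out)
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, value in list(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and key in state:
                value.data = np.asarray(state[key], dtype=value.data.dtype).reshape(value.data.shape)
            elif isinstance(value, np.ndarray) and key in state:
                setattr(self, name, np.asarray(state[key], dtype=value.dtype).reshape(value.shape))
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=None, groups=1,
                 bias=True, rng=None, dtype=np.float32):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * kernel * kernel
        bound = math.sqrt(1.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(c_out, c_in // groups, kernel, kernel))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=c_out).astype(dtype),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-3, momentum=0.03, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = ag.mean_(x, axis=(0, 2, 3), keepdims=True)
            var = ag.mean_(ag.mul(ag.sub(x, mu), ag.sub(x, mu)), axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c)).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(self.running_var.dtype)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xn = ag.div(ag.sub(x, mu), ag.sqrt(ag.add(var, self.eps)))
        g = ag.reshape(self.gamma, (1, c, 1, 1))
        b = ag.reshape(self.beta, (1, c, 1, 1))
        return ag.add(ag.mul(xn, g), b)

    def fold_coeffs(self):
        """Return (scale, shift) such that eval-mode BN(x) = scale*x + shift."""
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return scale, shift


class SiLU(Module):
    def forward(self, x):
        return ag.silu(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel, stride=1, padding=None):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x):
        return ag.maxpool2d(x, self.kernel, self.stride, self.padding)


class Upsample2x(Module):
    def forward(self, x):
        return ag.upsample_nearest2x(x)


class ConvBNAct(Module):
    """Conv (no bias) + BatchNorm + SiLU — the detector's standard cell."""

    def __init__(self, c_in, c_out, kernel=1, stride=1, groups=1, act=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, stride, groups=groups, bias=False,
                           rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(c_out, dtype=dtype)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Adam(Module):
    """Adam optimizer over a parameter list (decoupled from any framework)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__()
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
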