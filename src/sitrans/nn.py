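"""Neural-network layers and optimizers on top of the autodiff engine.

Conventions follow the package's training recipe: 3x3 stride-1
convolutions with same padding, batch normalization + ReLU after
convolutions, 2x2 max pooling for downsampling, bilinear upsampling for
upsampling, He initialization for convolution and linear weights, and
Adam with beta1 = 0.5.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = name
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: np.array(v, copy=True) for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.data = np.array(state[k], dtype=np.float64)
        for k, _ in self.named_buffers():
            self._set_buffer_by_path(k, np.array(state[k], copy=True))

    def _set_buffer_by_path(self, path, value):
        obj = self
        *parts, last = path.split(".")
        for part in parts:
            obj = getattr(obj, part)
        object.__setattr__(obj, last, value)

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, rng, padding=None):
        super().__init__()
        if padding is None:
            padding = (kernel_size - 1) // 2
        self.padding = padding
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Tensor(
            he_normal(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x):
        out = ad.conv2d(x, self.weight, padding=self.padding)
        return out + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.weight = Tensor(
            he_normal(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias.reshape(1, -1)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            object.__setattr__(
                self,
                "running_mean",
                (1 - m) * self.running_mean + m * mean.data.reshape(-1),
            )
            object.__setattr__(
                self,
                "running_var",
                (1 - m) * self.running_var + m * var.data.reshape(-1),
            )
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mean) * ((var + self.eps) ** -0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    x = x.reshape(n, c, h // 2, 2, w // 2, 2)
    x = ad.tmax(x, axis=5)
    return ad.tmax(x, axis=3)


_UPSAMPLE_CACHE: dict = {}


def _upsample_indices(size: int):
    """Bilinear x2 source indices/weights (half-pixel-center convention)."""
    if size in _UPSAMPLE_CACHE:
        return _UPSAMPLE_CACHE[size]
    coords = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
    coords = np.clip(coords, 0, size - 1)
    i0 = np.clip(np.floor(coords).astype(np.int64), 0, size - 2)
    frac = coords - i0
    _UPSAMPLE_CACHE[size] = (i0, frac)
    return i0, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    r0, fr = _upsample_indices(h)
    c0, fc = _upsample_indices(w)
    frt = Tensor(fr.reshape(1, 1, -1, 1))
    top = x[:, :, r0, :]
    bot = x[:, :, r0 + 1, :]
    rows = top * (1.0 - frt) + bot * frt
    fct = Tensor(fc.reshape(1, 1, 1, -1))
    left = rows[:, :, :, c0]
    right = rows[:, :, :, c0 + 1]
    return left * (1.0 - fct) + right * fct


class ConvBlock(Module):
    """(Conv3x3 -> BN -> ReLU) x2."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x):
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))


class Adam:
    """Adam optimizer (beta1 defaults to 0.5 per the training recipe)."""

    def __init__(self, params, lr=1e-3, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self):
        return {
            "t": self.t,
            "m": [a.copy() for a in self.m],
            "v": [a.copy() for a in self.v],
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.array(a) for a in state["m"]]
        self.v = [np.array(a) for a in state["v"]]


def step_module(optimizer: Adam, module: Module, loss: Tensor):
    """Backprop ``loss`` into ``module``'s parameters and apply one update."""
    params = module.parameters()
    grads = ad.grad(loss, params)
    optimizer.step(grads)
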