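"""Neural-network layers and optimizers on top of :mod:`mmha.autodiff`.

Initialisation is fan-in scaled and fully determined by the generator passed
to each layer, so models built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d, mac_counting

__all__ = [
    "Module", "Sequential", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm",
    "MaxPool2d", "GELU", "ReLU", "GlobalAvgPool", "SqueezeExcite",
    "SGD", "Adam", "count_params", "count_params_macs",
]


class Module:
    """Base class: parameter collection, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        params.extend(m.parameters())
        for _, child in self._children():
            params.extend(child.parameters())
        # preserve order, drop duplicates
        seen, uniq = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                uniq.append(p)
        return uniq

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor):
                state[prefix + name] = v.data
            elif isinstance(v, np.ndarray):  # buffers (running stats)
                state[prefix + name] = v
        for name, child in self._children():
            state.update(child.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, v in list(vars(self).items()):
            key = prefix + name
            if isinstance(v, Tensor) and key in state:
                v.data = np.asarray(state[key], dtype=v.data.dtype).reshape(v.data.shape)
            elif isinstance(v, np.ndarray) and key in state:
                setattr(self, name, np.asarray(state[key], dtype=v.dtype).reshape(v.shape))
        for name, child in self._children():
            child.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Tensor(
            _he_init(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) \
            if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel, with running stats."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mean
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc / (var + self.eps).sqrt()
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mean) * (1.0 / np.sqrt(var + self.eps))
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        xc = x - mean
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C) mean over the spatial plane."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class SqueezeExcite(Module):
    """Channel attention: global pool -> bottleneck MLP -> sigmoid gates."""

    def __init__(self, channels: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, int(round(channels * ratio)))
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        B, C = g.shape
        return x * g.reshape(B, C, 1, 1)


# ------------------------------------------------------------------ optimizers


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.0):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam:
    """Adam / AdamW.  ``decoupled_weight_decay=True`` gives AdamW."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled_weight_decay: bool = True):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled_weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ------------------------------------------------------------------- counting


def count_params(model: Module) -> int:
    """Total trainable parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def count_params_macs(model: Module, *input_shapes: tuple[int, ...]):
    """(trainable parameters, multiply-accumulates for one forward pass).

    MACs are measured by running a single-item forward pass with conv/matmul
    instrumentation; one MAC is counted as one FLOP, the convention used in
    published model-complexity tables.
    """
    was_training = model.training
    model.eval()
    inputs = [Tensor(np.zeros((1,) + tuple(s), np.float32)) for s in input_shapes]
    with mac_counting() as mc:
        model(*inputs)
    if was_training:
        model.train()
    return count_params(model), mc.total
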