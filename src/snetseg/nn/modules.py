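"""Layer containers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Base class: tracks parameters, buffers and train/eval mode."""

    def __init__(self):
        self.training = True

    # attribute walk in insertion order gives deterministic naming
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and not val.requires_grad and name.startswith("running_"):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
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

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.data.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(d)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for name, t in own.items():
            arr = np.asarray(d[name])
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {t.data.shape}")
            t.data = arr.astype(t.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """'Same' 2D convolution with odd kernel, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, n_ch, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros((1, n_ch, 1, 1), dtype=np.float32))
        self.running_var = Tensor(np.ones((1, n_ch, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batchnorm2d

        if self.training:
            mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
            var = x.data.var(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = ((1 - m) * self.running_mean.data
                                      + m * mu.astype(np.float32))
            self.running_var.data = ((1 - m) * self.running_var.data
                                     + m * var.astype(np.float32))
            return batchnorm2d(x, self.gamma, self.beta, self.eps, mu, var, True)
        return batchnorm2d(x, self.gamma, self.beta, self.eps,
                           self.running_mean.data.astype(x.data.dtype),
                           self.running_var.data.astype(x.data.dtype), False)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
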