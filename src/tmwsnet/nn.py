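"""Layers and optimizer built on the autodiff engine.

Weight initialisation is always driven by an explicit ``numpy`` Generator so
that model construction is bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "BatchNorm1d", "MLP", "Adam"]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(value):
        if isinstance(value, (Parameter, Module)):
            yield value
        elif isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._walk(item)

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            for item in Module._walk(v):
                if isinstance(item, Parameter):
                    params.append(item)
                else:
                    params.extend(item.parameters())
        return params

    def modules(self):
        yield self
        for v in self.__dict__.values():
            for item in Module._walk(v):
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

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module state (parameters + buffers)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays):
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state size mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        super().__init__()
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class BatchNorm1d(Module):
    """Normalisation over the point/group axis (axis 0) of an (N, c) input.

    Training uses batch statistics (falling back to running statistics when
    N == 1); inference uses running statistics.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (mu.data[0] - self.running_mean)
            self.running_var += self.momentum * (var.data[0] - self.running_var)
            return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        return xc * Tensor(1.0 / np.sqrt(self.running_var + self.eps)) * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with ReLU, the workhorse of the position/SSM paths."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng, zero_init=zero_init)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adam:
    """Adam with decoupled state, operating in place on parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
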