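"""Trainable layers over the autodiff backend."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, conv2d, conv_transpose2x2


class Module:
    """Minimal parameter container with train/eval state."""

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    training: bool = True

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.astype(DTYPE).copy()


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 convolution; padding chosen to preserve spatial size."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = Tensor(_fan_in_uniform(rng, (cout, cin, k, k), fan_in), requires_grad=True)
        self.b = Tensor(_fan_in_uniform(rng, (cout,), fan_in), requires_grad=True)
        if k % 2 == 1:
            p = (k - 1) // 2
            self.padding = (p, p, p, p)
        else:
            # even kernels: asymmetric padding keeps output size equal to input
            self.padding = (k // 2 - 1, k // 2, k // 2 - 1, k // 2)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.padding)


class ConvTranspose2x2(Module):
    """2x2 stride-2 up-convolution (spatial doubling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin  # each output pixel sees one input pixel per channel
        self.w = Tensor(_fan_in_uniform(rng, (cin, cout, 2, 2), fan_in), requires_grad=True)
        self.b = Tensor(_fan_in_uniform(rng, (cout,), fan_in), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, c, 1, 1), dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Adam:
    """Adam optimizer with optional decoupled L2 handled by the loss itself."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
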