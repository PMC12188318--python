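"""Small neural-network building blocks on top of :mod:`livertrack.autodiff`.

Layers hold their parameters as ``Tensor`` objects with ``requires_grad=True``
and expose them through ``parameters()`` for the Adam optimizer. Weight
initialization is He-style and driven by an explicit ``numpy.random.Generator``
so every training run is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv3d, relu

__all__ = ["Module", "Linear", "Conv2d", "Conv3d", "Adam",
           "timestep_embedding"]


class Module:
    """Base class: collects parameters from attributes, recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(arr, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, stride: int = 1, pad: int | None = None):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, stride: int = 1, pad: int | None = None):
        scale = np.sqrt(2.0 / (c_in * k * k * k))
        self.w = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class MLP(Module):
    """Shared per-point multi-layer perceptron with ReLU between layers."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x


class Adam:
    """Adam with the standard bias correction; operates in place."""

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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def timestep_embedding(t: int, width: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of a diffusion timestep, shape (width,)."""
    half = width // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half, 1))
    args = t * freqs
    emb = np.concatenate([np.sin(args), np.cos(args)])
    if emb.size < width:
        emb = np.concatenate([emb, np.zeros(width - emb.size)])
    return emb
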