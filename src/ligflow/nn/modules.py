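"""Minimal neural-network modules on top of the autodiff engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "Adam"]


class Module:
    """Base class: tracks parameters and sub-modules by attribute assignment."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis, Glorot-uniform initialised."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, gain: float = 1.0):
        bound = gain * np.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class MLP(Module):
    """Two linear layers with SiLU activation (extra hidden layers optional)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator,
                 n_hidden: int = 1):
        layers = [Linear(d_in, d_hidden, rng)]
        for _ in range(n_hidden - 1):
            layers.append(Linear(d_hidden, d_hidden, rng))
        layers.append(Linear(d_hidden, d_out, rng))
        self.layers = layers

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).silu()
        return self.layers[-1](x)


class LayerNorm(Module):
    """Normalisation over the last axis with learned scale and shift."""

    def __init__(self, d: int, eps: float = 1e-6):
        self.scale = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self._eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self._eps) ** -0.5) * self.scale + self.shift


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, grad_clip: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.grad_clip is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.grad_clip:
                scale = self.grad_clip / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
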