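"""Layer and optimizer primitives on top of the autodiff engine."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from . import autodiff as ad
from .autodiff import Var


class Module:
    """Base class: anything exposing a named parameter dictionary.

    Submodules are discovered from instance attributes (including lists of
    modules), giving stable dotted parameter names for checkpointing and
    the fine-tuning weight-surgery audit.
    """

    def parameters(self) -> dict[str, Var]:
        params: dict[str, Var] = {}
        for name, value in vars(self).items():
            if isinstance(value, Var) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for k, v in value.parameters().items():
                    params[f"{name}.{k}"] = v
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            params[f"{name}.{i}.{k}"] = v
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for v in self.parameters().values():
            v.zero_grad()

    def n_parameters(self) -> int:
        return sum(v.data.size for v in self.parameters().values())


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.dilation = dilation
        self.w = Var(he_init(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.b = Var(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Var) -> Var:
        return ad.conv2d(x, self.w, self.b, dilation=self.dilation)

    def reinitialize(self, rng: np.random.Generator) -> None:
        """Redraw weights from the init distribution (fresh biases)."""
        cout, cin, kh, kw = self.w.data.shape
        self.w.data = he_init(rng, (cout, cin, kh, kw), cin * kh * kw)
        self.b.data = np.zeros(cout)


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Var(he_init(rng, (nin, nout), nin), requires_grad=True)
        self.b = Var(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Var) -> Var:
        return ad.add(ad.matmul(x, self.w), self.b)


class Adam:
    """Adam with optional per-parameter learning-rate multipliers."""

    def __init__(self, params: Mapping[str, Var], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_mult: Mapping[str, float] | None = None):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_mult = dict(lr_mult or {})
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in self.params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            lr = self.lr * self.lr_mult.get(k, 1.0)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
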