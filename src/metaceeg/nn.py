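"""Small neural-network building blocks over the autodiff engine.

Layers hold their parameters as `autodiff.Tensor`s; fresh parameter Tensors
are rebuilt from plain numpy state before every forward pass by the trainer,
so graphs never leak across optimization steps.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: a list of named numpy parameters + a forward over Tensors."""

    def __init__(self):
        self._params: dict[str, np.ndarray] = {}
        self._tensors: dict[str, Tensor] = {}

    def add_param(self, name: str, value: np.ndarray) -> None:
        self._params[name] = np.asarray(value, dtype=np.float64)

    def parameters(self) -> dict[str, np.ndarray]:
        return self._params

    def refresh(self) -> None:
        """Wrap current numpy parameters in fresh leaf Tensors."""
        self._tensors = {k: Tensor(v) for k, v in self._params.items()}

    def param_tensors(self) -> list[Tensor]:
        return list(self._tensors.values())

    def p(self, name: str) -> Tensor:
        return self._tensors[name]

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # state round-trip (checkpointing)
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self._params:
            self._params[k] = np.array(state[k], dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.add_param("w", _glorot(rng, n_in, n_out, (n_in, n_out)))
        self.add_param("b", np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.p("w") + self.p("b")


class Conv1d(Module):
    """Stride-1 'same' convolution, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        assert kernel % 2 == 1
        self.kernel = kernel
        self.pad = kernel // 2
        fan = c_in * kernel
        self.add_param("w", _glorot(rng, fan, c_out * kernel, (c_out, c_in, kernel)))
        self.add_param("b", np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        y = ad.conv1d(x, self.p("w"), pad=self.pad)
        return y + ad.reshape(self.p("b"), (1, -1, 1))


class Sequential(Module):
    def __init__(self, *blocks):
        super().__init__()
        self.blocks = list(blocks)

    def refresh(self) -> None:
        for b in self.blocks:
            if isinstance(b, Module):
                b.refresh()

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, b in enumerate(self.blocks):
            if isinstance(b, Module):
                for k, v in b.parameters().items():
                    out[f"{i}.{k}"] = v
        return out

    def param_tensors(self) -> list[Tensor]:
        out = []
        for b in self.blocks:
            if isinstance(b, Module):
                out.extend(b.param_tensors())
        return out

    def set_flat(self, flats: dict[str, np.ndarray]) -> None:
        for i, b in enumerate(self.blocks):
            if isinstance(b, Module):
                for k in b.parameters():
                    b._params[k] = np.array(flats[f"{i}.{k}"], dtype=np.float64)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.set_flat(state)

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x) if isinstance(b, Module) else b(x)
        return x


# -- stateless layer helpers usable inside Sequential -----------------------

def LeakyReLU(slope: float = 0.2):
    return lambda x: ad.leaky_relu(x, slope)


def Tanh():
    return ad.tanh


def Flatten():
    return lambda x: ad.reshape(x, (x.shape[0], -1))


def AvgPool1d(k: int):
    def op(x: Tensor) -> Tensor:
        B, C, L = x.shape
        return ad.reshape(x, (B, C, L // k, k)).mean(axis=3)
    return op


def UpsampleNearest(k: int = 2):
    def op(x: Tensor) -> Tensor:
        B, C, L = x.shape
        x4 = ad.reshape(x, (B, C, L, 1))
        return ad.reshape(ad.broadcast_to(x4, (B, C, L, k)), (B, C, L * k))
    return op


class Adam:
    """Plain Adam over a module's numpy parameter dict."""

    def __init__(self, module: Module, lr=1e-4, betas=(0.5, 0.9), eps=1e-8):
        self.module = module
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in module.parameters().items()}
        self.v = {k: np.zeros_like(v) for k, v in module.parameters().items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        params = self.module.parameters()
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}


def grads_by_name(module: Module, loss: Tensor) -> dict[str, np.ndarray]:
    """Backprop `loss` and return numpy gradients keyed like parameters()."""
    names = list(module.parameters().keys())
    tensors = module.param_tensors()
    assert len(names) == len(tensors)
    gs = ad.grad(loss, tensors)
    return {n: g.data for n, g in zip(names, gs)}
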