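"""Neural-network layers and the Adam optimizer on top of :mod:`autodiff`.

Layers follow the familiar module pattern: parameters are ``Tensor`` leaves
with ``requires_grad=True``; ``Module.parameters()`` walks attributes and
sub-modules recursively.  Initialization is the uniform fan-in scheme
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) drawn from a generator owned by the model,
so a fixed seed reproduces the network bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            if isinstance(obj, Tensor) and obj.requires_grad:
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for p in obj.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            if isinstance(obj, Module):
                mods.extend(obj.modules())
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict):
        for name, obj in self.__dict__.items():
            if isinstance(obj, Tensor):
                out[prefix + name] = obj.data.copy()
            elif isinstance(obj, np.ndarray):
                out[prefix + name] = obj.copy()
            elif isinstance(obj, Module):
                obj._collect_state(f"{prefix}{name}.", out)
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        item._collect_state(f"{prefix}{name}.{i}.", out)

    def load_state_dict(self, state: dict[str, np.ndarray]):
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict):
        for name, obj in self.__dict__.items():
            key = prefix + name
            if isinstance(obj, Tensor):
                obj.data = state[key].astype(obj.data.dtype).reshape(obj.data.shape)
            elif isinstance(obj, np.ndarray):
                self.__dict__[name] = state[key].astype(obj.dtype).reshape(obj.shape)
            elif isinstance(obj, Module):
                obj._load_state(f"{key}.", state)
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        item._load_state(f"{key}.{i}.", state)


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Tensor(_uniform_fan_in(rng, (in_features, out_features),
                                             in_features), requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, (out_features,), in_features),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim > 2:  # flatten leading axes for the 2-D matmul
            lead = x.shape[:-1]
            h = ad.matmul(ad.reshape(x, (-1, x.shape[-1])), self.weight)
            return ad.reshape(h + self.bias, (*lead, self.weight.shape[1]))
        return ad.matmul(x, self.weight) + self.bias

    __call__ = forward


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        fan_in = in_channels * kernel
        self.weight = Tensor(
            _uniform_fan_in(rng, (out_channels, in_channels, kernel), fan_in),
            requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, (out_channels,), fan_in),
                           requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, self.stride)

    __call__ = forward


class BatchNorm1d(Module):
    """Per-feature normalization over (batch, time) for (B, F, T) inputs."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = Tensor(np.ones(num_features, dtype=DTYPE),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=DTYPE),
                           requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
        xhat = (x - mu) * ad.power(var + Tensor(np.asarray(self.eps, DTYPE)),
                                   -0.5)
        return xhat * ad.reshape(self.gamma, (1, -1, 1)) \
            + ad.reshape(self.beta, (1, -1, 1))

    __call__ = forward


class LSTM(Module):
    """Single-direction LSTM; returns the full hidden-state sequence.

    Gate layout along the last axis of the projections is (i, f, g, o).
    The input projection for all time steps is computed in one matmul; only
    the hidden-to-hidden recurrence runs step by step.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, reverse: bool = False):
        H = hidden_size
        self.w_ih = Tensor(_uniform_fan_in(rng, (input_size, 4 * H), H),
                           requires_grad=True)
        self.w_hh = Tensor(_uniform_fan_in(rng, (H, 4 * H), H),
                           requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, (4 * H,), H),
                           requires_grad=True)
        self.hidden_size = H
        self.reverse = reverse

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H = self.hidden_size
        xp = ad.reshape(ad.matmul(ad.reshape(x, (-1, D)), self.w_ih)
                        + self.bias, (B, T, 4 * H))
        steps = ad.unbind_time(xp)
        h = Tensor(np.zeros((B, H), dtype=DTYPE))
        c = Tensor(np.zeros((B, H), dtype=DTYPE))
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        outputs: list[Tensor] = [None] * T  # type: ignore[list-item]
        for t in order:
            gates = steps[t] + ad.matmul(h, self.w_hh)
            i = ad.sigmoid(gates[:, 0 * H:1 * H])
            f = ad.sigmoid(gates[:, 1 * H:2 * H])
            g = ad.tanh(gates[:, 2 * H:3 * H])
            o = ad.sigmoid(gates[:, 3 * H:4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outputs[t] = ad.reshape(h, (B, 1, H))
        return ad.concat(outputs, axis=1)

    __call__ = forward


class BiLSTM(Module):
    """Forward and backward LSTMs, hidden states concatenated per step."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        self.fwd = LSTM(input_size, hidden_size, rng, reverse=False)
        self.bwd = LSTM(input_size, hidden_size, rng, reverse=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.concat([self.fwd(x), self.bwd(x)], axis=2)

    __call__ = forward


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
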