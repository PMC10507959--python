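"""Parameter containers and layers built on the autodiff core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .core import Tensor, conv1d, gather_rows, matmul, mul, add


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        # Parameters stay trainable even when created under no_grad.
        self.requires_grad = True


class Module:
    """Base class: recursive parameter discovery by attribute name.

    Lists of modules are traversed with a numeric suffix, mirroring the
    ``layers.0.weight`` naming convention common in deep-learning code.
    """

    training: bool = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, value in vars(self).items():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(glorot(rng, (out_dim, in_dim), in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, _t(self.weight)), self.bias)


def _t(p: Parameter) -> Tensor:
    """Transpose view of a parameter that routes gradients back."""
    out = Tensor(p.data.T, requires_grad=True, parents=(p,), backward=lambda g: p._accumulate(g.T))
    return out


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator, padding_idx: int | None = 0):
        w = rng.normal(0.0, 0.05, size=(vocab_size, dim))
        if padding_idx is not None:
            w[padding_idx] = 0.0
        self.weight = Parameter(w)

    def __call__(self, ids: np.ndarray) -> Tensor:
        flat = np.asarray(ids).reshape(-1)
        out = gather_rows(self.weight, flat)
        from .core import reshape

        return reshape(out, np.asarray(ids).shape + (self.weight.data.shape[1],))


class Conv1d(Module):
    """Valid convolution along the sequence axis; input (B, L, Cin)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        self.weight = Parameter(glorot(rng, (out_channels, kernel_size, in_channels), fan_in, out_channels))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel_size = kernel_size

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Needs an explicit RNG."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1): {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return mul(x, Tensor(mask))
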