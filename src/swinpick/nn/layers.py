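"""Basic trainable layers built on the autograd tensors."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Mlp"]


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            params.extend(_collect(value))
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in self.__dict__.items():
            out.extend(_collect_named(value, f"{prefix}{name}"))
        return out


def _collect(value):
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name):
    if isinstance(value, Parameter):
        return [(name, value)]
    if isinstance(value, Module):
        return value.named_parameters(prefix=name + ".")
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_named(v, f"{name}.{i}"))
        return out
    return []


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, eps=self.eps)


class Mlp(Module):
    """Two-layer feed-forward block with GELU; hidden width = ratio * dim."""

    def __init__(self, dim: int, rng: np.random.Generator, ratio: int = 4,
                 dropout: float = 0.0):
        self.fc1 = Linear(dim, ratio * dim, rng)
        self.fc2 = Linear(ratio * dim, dim, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        h = self.fc1(x).gelu()
        if training and self.dropout > 0 and rng is not None:
            h = h.dropout(self.dropout, rng)
        y = self.fc2(h)
        if training and self.dropout > 0 and rng is not None:
            y = y.dropout(self.dropout, rng)
        return y
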