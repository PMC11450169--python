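"""Neural-network module system over :mod:`hemafuse.autodiff`.

Provides the usual hierarchy: :class:`Parameter`, :class:`Module` with
recursive parameter discovery and a flat ``state_dict`` keyed by dotted paths
(``blocks.3.attn.qkv.weight`` ...), plus the two layers a transformer needs,
:class:`Linear` and :class:`LayerNorm`.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "Buffer", "Module", "ModuleList", "Linear", "LayerNorm"]


class Parameter(Tensor):
    """A trainable tensor (leaf of the autodiff graph)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Buffer:
    """Non-trainable state that persists in ``state_dict`` (running stats)."""

    __slots__ = ("data",)

    def __init__(self, data):
        self.data = np.asarray(data, dtype=np.float64)


class ModuleList(list):
    """A list of sub-modules that participates in parameter discovery."""


class Module:
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_parameters(f"{full}.{i}.")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, Buffer]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Buffer):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_buffers(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        out.update({k: b.data.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own: dict[str, Parameter | Buffer] = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if strict and (missing or unexpected):
            raise KeyError(
                f"state dict mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(unexpected)}"
            )
        for key, value in state.items():
            if key not in own:
                continue
            if own[key].data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch for '{key}': "
                    f"{own[key].data.shape} vs {value.shape}"
                )
            own[key].data = np.asarray(value, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map ``y = x @ W + b`` with W of shape (in_features, out_features)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 std: float = 0.02, zero_init: bool = False, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, std, size=(in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered / (var + self.eps).sqrt()
        return xhat * self.weight + self.bias
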