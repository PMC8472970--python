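"""Minimal building blocks for the NumPy conv-net engine.

The engine implements exactly what the segmentation network needs:
modules hold :class:`Parameter` leaves, cache whatever the backward
pass requires during ``forward``, and accumulate gradients into
``Parameter.grad`` during ``backward``.  Everything runs in float32.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

#: working precision of the engine; float64 is available for gradient
#: checking (see :func:`set_dtype`), float32 for speed.
DTYPE = np.float32


def set_dtype(dt) -> None:
    """Set the engine's working dtype (affects modules built afterwards)."""
    global DTYPE
    DTYPE = np.dtype(dt).type


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: recursive parameter/buffer discovery via attributes."""

    #: attribute names of non-learnable state arrays (e.g. BN running stats)
    buffer_names: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for k, v in vars(self).items():
            if isinstance(v, Module):
                yield k, v
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        yield f"{k}.{i}", u

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + k, v
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in self.buffer_names:
            yield prefix + k, getattr(self, k)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    # -- mode / gradients ----------------------------------------------
    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- (de)serialization ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {k: (owner, name) for owner, name, k in self._buffer_owners()}
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data[...] = value
            elif kind == "buffer":
                owner, attr = buffers[name]
                setattr(owner, attr, np.ascontiguousarray(value, dtype=DTYPE))
            else:
                raise KeyError(f"unrecognized state entry {key!r}")

    def _buffer_owners(self, prefix: str = ""):
        for k in self.buffer_names:
            yield self, k, prefix + k
        for name, child in self._children():
            yield from child._buffer_owners(f"{prefix}{name}.")

    # -- interface ------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    """Chain of modules; backward runs the chain in reverse."""

    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
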