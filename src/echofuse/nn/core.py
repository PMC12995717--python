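"""Minimal CPU neural-network kernel with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``, so
intermediate activations and gradients (needed for grad-CAM and guided
backpropagation) are available at any module boundary without a tape.
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np


class Parameter:
    """A trainable array with an accompanying gradient buffer."""

    __slots__ = ("data", "grad")

    def __init__(self, shape: tuple[int, ...], dtype=np.float32):
        self.data = np.zeros(shape, dtype=dtype)
        self.grad = np.zeros(shape, dtype=dtype)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; subclasses implement ``forward`` and ``backward``."""

    def __init__(self):
        self.training = True

    # -- graph traversal ---------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def named_members(self, prefix: str = "") -> Iterator[tuple[str, object, str]]:
        """Yield (name, object, kind) for parameters and buffers, DFS order."""
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Parameter):
                yield name, value, "param"
            elif isinstance(value, Module):
                yield from value.named_members(name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_members(f"{name}.{i}.")
        for attr in getattr(self, "buffer_names", ()):
            yield f"{prefix}{attr}", self, f"buffer:{attr}"

    def parameters(self) -> Iterator[Parameter]:
        for _, obj, kind in self.named_members():
            if kind == "param":
                yield obj

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, obj, kind in self.named_members():
            if kind == "param":
                state[name] = obj.data.copy()
            else:
                attr = kind.split(":", 1)[1]
                state[name] = np.array(getattr(obj, attr), copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, obj, kind in self.named_members():
            if name not in state:
                raise KeyError(f"missing state entry {name!r}")
            if kind == "param":
                obj.data = np.array(state[name], dtype=obj.data.dtype, copy=True)
            else:
                attr = kind.split(":", 1)[1]
                setattr(obj, attr, np.array(state[name], copy=True))

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def initialize(self, rng: np.random.Generator) -> "Module":
        """He-style init of every submodule, in deterministic DFS order."""
        for m in self.modules():
            reset = getattr(m, "reset_parameters", None)
            if reset is not None:
                reset(rng)
        return self

    # -- compute -----------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Lambda(Module):
    """Stateless shape-juggling layer defined by a pair of callables."""

    def __init__(self, fn: Callable, inverse: Callable):
        super().__init__()
        self.fn = fn
        self.inverse = inverse

    def forward(self, x):
        self._in_shape = x.shape
        return self.fn(x)

    def backward(self, grad):
        return self.inverse(grad, self._in_shape)
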