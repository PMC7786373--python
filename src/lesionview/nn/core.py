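"""Minimal layer/module machinery for the numpy network engine.

Every layer owns its parameters (``Parameter`` objects with ``.data`` and
``.grad``) and implements an explicit ``forward``/``backward`` pair; there is
no autograd tape.  Modules form a named tree so that parameters and buffers
can be enumerated with dotted names (``layer1.0.conv1.weight``), which is what
checkpointing, parameter counting and pretrained-weight transfer operate on.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: a named tree of sub-modules, parameters and buffers."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True
        self.rng: np.random.Generator | None = None

    # -- registration -----------------------------------------------------
    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        setattr(self, name, module)
        return module

    def add_param(self, name: str, array: np.ndarray) -> Parameter:
        p = Parameter(array)
        self._params[name] = p
        setattr(self, name, p)
        return p

    def add_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        arr = np.asarray(array)
        self._buffers[name] = arr
        setattr(self, name, arr)
        return arr

    def set_buffer(self, name: str, array: np.ndarray) -> None:
        self._buffers[name] = array
        setattr(self, name, array)

    # -- traversal --------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- mode / rng -------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def set_rng(self, rng: np.random.Generator) -> "Module":
        """Attach one generator to every sub-module (dropout noise etc.)."""
        for _, m in self.named_modules():
            m.rng = rng
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad.fill(0.0)

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, _ in list(self.named_buffers()):
            self._assign_buffer(name, state[name])

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        mod: Module = self
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod.set_buffer(parts[-1], np.asarray(value, dtype=mod._buffers[parts[-1]].dtype).copy())

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            self.add_module(str(i), layer)

    @property
    def layers(self) -> list[Module]:
        return list(self._modules.values())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He/Kaiming uniform initialisation for ReLU networks."""
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)
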