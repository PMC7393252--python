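"""Parameter container and module base class."""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient.

    ``trainable=False`` freezes the value: optimizers skip it and callers may
    rely on it staying bit-identical across training.
    """

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.trainable = trainable

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: children registered via attribute assignment."""

    def __init__(self):
        self._params: list[Parameter] = []
        self._children: list["Module"] = []
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", []).append(value)
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", []).append(value)
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            self.__dict__.setdefault("_children", []).extend(value)
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for child in self._children:
            out.extend(child.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        self.training = True
        for child in self._children:
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for child in self._children:
            child.eval()
        return self

    # -- weight (de)serialization ------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping covering parameters and buffers."""
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self._params):
            state[f"{prefix}p{i}"] = p.data
        for name, buf in getattr(self, "_buffers", {}).items():
            state[f"{prefix}{name}"] = buf
        for i, child in enumerate(self._children):
            state.update(child.state_dict(prefix=f"{prefix}m{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, p in enumerate(self._params):
            arr = state[f"{prefix}p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {prefix}p{i}: "
                    f"checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data[...] = arr
        for name in getattr(self, "_buffers", {}):
            self._buffers[name][...] = state[f"{prefix}{name}"]
        for i, child in enumerate(self._children):
            child.load_state_dict(state, prefix=f"{prefix}m{i}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self.__dict__.setdefault("_buffers", {})[name] = value

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules_list = list(modules)

    def forward(self, x):
        for m in self.modules_list:
            x = m.forward(x)
        return x

    def backward(self, gy):
        for m in reversed(self.modules_list):
            gy = m.backward(gy)
        return gy
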