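"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=p.data.dtype)


class Conv2d(Module):
    """Stride-1 convolution, 'same' padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / in_f)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_f, out_f)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
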