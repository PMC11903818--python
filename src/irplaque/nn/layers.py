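"""Convolutional building blocks on top of the autodiff engine.

Layout convention is NHWC (batch, row, col, channel) throughout; weights are
stored as 2-D matrices so every convolution reduces to an im2col matmul.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, pad2d, patches

__all__ = ["Param", "Conv2d", "Conv1x1", "ConvTranspose2x2", "DoubleConv", "Module"]


class Param(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny container protocol: recursively collects ``Param`` attributes."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()


def _he(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...], gain: float = 2.0):
    return rng.normal(0.0, np.sqrt(gain / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """3x3 same-padding convolution stored as a (9*Cin, Cout) matrix."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_he(rng, 9 * cin, (9 * cin, cout)))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        p = patches(pad2d(x, 1), 3)
        cout = self.w.shape[1]
        y = p.reshape(n * h * w, 9 * c) @ self.w
        return y.reshape(n, h, w, cout) + self.b


class Conv1x1(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, gain: float = 1.0):
        self.w = Param(_he(rng, cin, (cin, cout), gain))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        y = x.reshape(n * h * w, c) @ self.w
        return y.reshape(n, h, w, self.w.shape[1]) + self.b


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (non-overlapping up-convolution).

    Each input pixel expands into a 2x2 output block, so the op is a matmul
    against a (Cin, 4*Cout) matrix followed by a block rearrangement.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cout = cout
        self.w = Param(_he(rng, cin, (cin, 4 * cout)))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        y = x.reshape(n * h * w, c) @ self.w  # (N*H*W, 2*2*Cout)
        y = y.reshape(n, h, w, 2, 2, self.cout)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.cout)
        return y + self.b


class DoubleConv(Module):
    """Two 3x3 conv + leaky-ReLU blocks — the standard U-Net level.

    The small negative slope keeps units trainable if an early optimizer
    step drives their pre-activations negative across the whole batch.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv2d(cin, cout, rng)
        self.c2 = Conv2d(cout, cout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).leaky_relu()).leaky_relu()
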