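"""Depth-reduced U-Net producing a bounded activation map.

The encoder halves the spatial size three times (64 -> 32 -> 16 -> 8) while
doubling feature widths; the decoder restores resolution with 2x2 stride-2
transposed convolutions and skip connections; a final 1x1 convolution with a
sigmoid squashes the output into [0, 1].  With the default base width of 64
and depth 3 the bottleneck is 8 x 8 x 512.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .layers import Conv1x1, ConvTranspose2x2, DoubleConv, Module

__all__ = ["ModelSpec", "CompSegNet", "build_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    in_channels
        Spectral depth of the input cube (427 for the full 1800-948 cm^-1
        grid at 2 cm^-1).
    depth
        Number of pooling stages; spatial size must be divisible by 2**depth.
    base_width
        Feature maps of the first level; doubled at each stage, so the
        bottleneck carries ``base_width * 2**depth`` features.
    """

    in_channels: int
    depth: int = 3
    base_width: int = 64

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.depth < 1 or self.base_width < 1:
            raise ValueError("depth and base_width must be >= 1")

    @property
    def bottleneck_features(self) -> int:
        return self.base_width * 2 ** self.depth


class CompSegNet(Module):
    def __init__(self, spec: ModelSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        # fixed affine input standardization (identity until calibrated);
        # set from training data so every spectral channel enters the first
        # convolution on a comparable scale
        self.input_mean = np.zeros(spec.in_channels, dtype=np.float32)
        self.input_scale = np.ones(spec.in_channels, dtype=np.float32)
        w = spec.base_width
        widths = [w * 2 ** i for i in range(spec.depth)]
        self.enc = [DoubleConv(spec.in_channels if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(spec.depth)]
        self.bottleneck = DoubleConv(widths[-1], 2 * widths[-1], rng)
        self.up = []
        self.dec = []
        prev = 2 * widths[-1]
        for i in reversed(range(spec.depth)):
            self.up.append(ConvTranspose2x2(prev, widths[i], rng))
            self.dec.append(DoubleConv(2 * widths[i], widths[i], rng))
            prev = widths[i]
        self.head = Conv1x1(prev, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Map (N, H, W, C) absorbance to an (N, H, W, 1) activation map."""
        _, h, w, c = x.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        if h % 2 ** self.spec.depth or w % 2 ** self.spec.depth:
            raise ValueError(f"spatial size must be divisible by {2 ** self.spec.depth}")
        x = (x + (-self.input_mean)) * self.input_scale
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = x.maxpool2()
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = dec(concat(up(x), skip, axis=-1))
        return self.head(x).sigmoid()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = super().state_dict()
        state["input_mean"] = self.input_mean.copy()
        state["input_scale"] = self.input_scale.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        state = dict(state)
        self.input_mean = np.asarray(state.pop("input_mean"), dtype=np.float32)
        self.input_scale = np.asarray(state.pop("input_scale"), dtype=np.float32)
        super().load_state_dict(state)

    def calibrate_input(self, data: np.ndarray) -> None:
        """Set the input standardization from sample spectra (N..., C)."""
        flat = np.asarray(data, dtype=np.float32).reshape(-1, self.spec.in_channels)
        self.input_mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.input_scale = (1.0 / np.maximum(sd, 1e-6)).astype(np.float32)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference helper: (N, H, W, C) array -> (N, H, W) activation maps."""
        out = self.forward(Tensor(np.ascontiguousarray(batch, dtype=np.float32)))
        return out.data[..., 0]


def build_model(spec: ModelSpec, seed: int) -> CompSegNet:
    """Construct a seeded-deterministic model (same seed, same weights)."""
    return CompSegNet(spec, seed)
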