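"""Pixel-level segmentation evaluation: precision, prevalence and the
purification factor.

The purification factor PF = PPV / PR expresses by what factor plaque
material is enriched in a mask-guided extraction relative to homogenizing
the whole section: a perfect mask reaches 1 / prevalence, a random mask
hovers around 1.  Per-sample PF values are averaged separately from the
pooled confusion because the two generally differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ihc_mask import BinaryMask

__all__ = [
    "PixelConfusion", "confusion", "ppv", "prevalence",
    "purification_factor", "binarize_activation", "overlay_confusion",
]


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: BinaryMask, truth: BinaryMask) -> PixelConfusion:
    """Pixel-by-pixel joint counts; the two masks must share one grid."""
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    p = pred.values
    t = truth.values
    return PixelConfusion(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def ppv(c: PixelConfusion) -> float | None:
    """Precision TP / (TP + FP); None when nothing was predicted positive."""
    denom = c.tp + c.fp
    if denom == 0:
        return None
    return c.tp / denom


def prevalence(c: PixelConfusion) -> float:
    """Truly positive fraction of all pixels: (TP + FN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion")
    return (c.tp + c.fn) / c.total


def purification_factor(c: PixelConfusion) -> float | None:
    """PF = PPV / PR; None when either term is undefined (no truth positives
    or no predicted positives)."""
    pr = prevalence(c)
    if pr == 0:
        return None
    p = ppv(c)
    if p is None:
        return None
    return p / pr


def overlay_confusion(pred: BinaryMask, truth: BinaryMask) -> np.ndarray:
    """Color-coded comparison image: TP green, FP red, FN blue, TN white."""
    if pred.shape != truth.shape:
        raise ValueError("grid mismatch")
    p, t = pred.values, truth.values
    img = np.ones((*p.shape, 3))
    img[p & t] = [0.0, 0.8, 0.0]
    img[p & ~t] = [0.9, 0.0, 0.0]
    img[~p & t] = [0.0, 0.0, 0.9]
    return img


def binarize_activation(a: np.ndarray, threshold: float = 0.5,
                        pixel_size: float = 4.25) -> BinaryMask:
    """Threshold an activation map (values >= threshold become foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return BinaryMask(np.asarray(a) >= threshold, pixel_size)
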