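"""Labeled 64x64 ROI samples, case-level splits and dihedral augmentation.

Samples pair an absorbance patch with its weak label and effective
background mask.  Splits are strictly by case: spectra of one subject never
appear in more than one of train / validation / test, which is the leakage
guard every weakly supervised medical-imaging study needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ihc_mask import BinaryMask, roi_label
from .phantom import CONN8, SceneTruth, SpectralCube

__all__ = [
    "RoiSample", "SplitSpec",
    "extract_rois", "split_by_case", "augment", "sample_positions",
]

logger = logging.getLogger(__name__)

ROI = 64


@dataclass
class RoiSample:
    patch: np.ndarray            # (64, 64, C) absorbance
    y: int                       # weak label
    effective_mask: np.ndarray   # (64, 64) binary; all ones when y == 0
    case_id: str
    sample_id: str
    origin: tuple[int, int]      # (row, col) of the top-left corner, 0-based

    def __post_init__(self):
        if self.patch.shape[:2] != (ROI, ROI):
            raise ValueError("patch must be 64x64 spatially")
        if self.y not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.y == 0 and not self.effective_mask.all():
            raise ValueError("negative samples must carry an all-ones mask")


@dataclass(frozen=True)
class SplitSpec:
    """Mapping of case_id to one of train / val / test."""

    assignment: dict

    def __post_init__(self):
        bad = {v for v in self.assignment.values()} - {"train", "val", "test"}
        if bad:
            raise ValueError(f"unknown partitions: {sorted(bad)}")


def extract_rois(cube: SpectralCube, mask: BinaryMask,
                 positions: list[tuple[int, int]], case_id: str = "case",
                 positive_fraction_threshold: float = 0.05) -> list[RoiSample]:
    """Cut labeled 64x64 windows at ``positions`` (top-left corners).

    Out-of-bounds windows are rejected with an error; windows whose positive
    fraction falls in the excluded (0, 5 %) band are dropped and counted.
    """
    h, w, _ = cube.shape
    samples: list[RoiSample] = []
    dropped = 0
    for i, (r, c) in enumerate(positions):
        if r < 0 or c < 0 or r + ROI > h or c + ROI > w:
            raise ValueError(f"ROI at ({r}, {c}) does not fit inside {h}x{w} cube")
        window = mask.values[r:r + ROI, c:c + ROI]
        y, eff, keep = roi_label(window, positive_fraction_threshold)
        if not keep:
            dropped += 1
            continue
        samples.append(RoiSample(
            patch=np.ascontiguousarray(cube.data[r:r + ROI, c:c + ROI, :]),
            y=y, effective_mask=eff, case_id=case_id,
            sample_id=f"{case_id}:{r}:{c}", origin=(r, c)))
    if dropped:
        logger.info("extract_rois: dropped %d window(s) in the excluded "
                    "(0, 5%%) positive-fraction band", dropped)
    return samples


def split_by_case(samples: list[RoiSample],
                  spec: SplitSpec) -> tuple[list[RoiSample], list[RoiSample], list[RoiSample]]:
    """Partition samples by their case assignment; unknown cases are rejected."""
    parts: dict[str, list[RoiSample]] = {"train": [], "val": [], "test": []}
    for s in samples:
        if s.case_id not in spec.assignment:
            raise ValueError(f"case {s.case_id!r} missing from split assignment")
        parts[spec.assignment[s.case_id]].append(s)
    return parts["train"], parts["val"], parts["test"]


def augment(sample: RoiSample, op_index: int) -> RoiSample:
    """Apply one of the 8 dihedral-group ops to patch and mask together.

    Ops 0-3 rotate by 90 degrees * op; ops 4-7 flip horizontally first, then
    rotate.  The weak label is geometric-invariant and unchanged.
    """
    if not 0 <= op_index <= 7:
        raise ValueError("op_index must be in 0..7")
    patch, m = sample.patch, sample.effective_mask
    if op_index >= 4:
        patch = patch[:, ::-1]
        m = m[:, ::-1]
    k = op_index % 4
    patch = np.rot90(patch, k, axes=(0, 1))
    m = np.rot90(m, k)
    return RoiSample(np.ascontiguousarray(patch), sample.y,
                     np.ascontiguousarray(m), sample.case_id,
                     sample.sample_id, sample.origin)


def sample_positions(truth: SceneTruth, n_negative: int | None = None,
                     seed: int = 0,
                     max_tries: int = 10000
                     ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Seeded surrogate for manual ROI selection.

    Returns ``(positive_positions, negative_positions)``: one window centred
    on every plaque component (clipped into bounds) plus ``n_negative``
    windows free of any plaque pixel (defaults to the number of positives,
    the balanced design).  Negative windows may contain folds and holes —
    exactly the structures amyloid-free ROIs should represent.  Keeping the
    two lists separate mirrors the expert curation step: the selector knows
    which windows are amyloid-free, so downstream labelling cannot be fooled
    by stain debris.
    """
    h, w = truth.plaque_mask.shape
    rng = np.random.default_rng(seed)
    positives: list[tuple[int, int]] = []
    objects = ndimage.find_objects(truth.plaque_labels)
    for sl in objects:
        if sl is None:
            continue
        cy = (sl[0].start + sl[0].stop) // 2
        cx = (sl[1].start + sl[1].stop) // 2
        r = int(np.clip(cy - ROI // 2, 0, h - ROI))
        c = int(np.clip(cx - ROI // 2, 0, w - ROI))
        positives.append((r, c))
    n_neg = len(positives) if n_negative is None else n_negative
    negatives: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(negatives) >= n_neg:
            break
        r = int(rng.integers(0, h - ROI + 1))
        c = int(rng.integers(0, w - ROI + 1))
        if not truth.plaque_mask[r:r + ROI, c:c + ROI].any():
            negatives.append((r, c))
    if len(negatives) < n_neg:
        logger.warning("sample_positions: only %d of %d negative windows found",
                       len(negatives), n_neg)
    return positives, negatives
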