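"""End-to-end orchestration on phantom cohorts.

A "cohort" is a set of synthetic cases, each one whole-slide scene with its
pseudo-IHC rendering.  ROI samples are drawn per case (every plaque
component contributes one window, matched by an equal number of
amyloid-free windows), labeled through the per-window IHC mask pipeline,
and split strictly at case level.  This is the reproducible surrogate for
the manual ROI selection a neuropathologist would perform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .compsegnet import TrainConfig, TransferParams, evaluate_split, train
from .ihc_mask import BinaryMask, MaskConfig, ihc_to_mask
from .nn import ModelSpec
from .phantom import (SceneTruth, SpectralCube, SpectralModel, StainParams,
                      WavenumberAxis, generate_scene, make_wavenumber_axis,
                      render_pseudo_ihc)
from .roi_dataset import ROI, RoiSample, SplitSpec, sample_positions, split_by_case
from .selection_metrics import select_model
from .seg_eval import binarize_activation
from .wsi import segment_wsi

logger = logging.getLogger(__name__)

__all__ = ["PhantomCase", "build_phantom_case", "build_phantom_cohort",
           "component_hit_rate", "reduced_axis"]


def reduced_axis(n_channels: int = 16) -> WavenumberAxis:
    """Compressed band grid spanning the full 1800-948 cm^-1 range."""
    step = (1800.0 - 948.0) / (n_channels - 1)
    return make_wavenumber_axis(1800.0, 948.0, step)


@dataclass
class PhantomCase:
    case_id: str
    cube: SpectralCube
    truth: SceneTruth
    ihc: np.ndarray
    slide_mask: BinaryMask
    samples: list[RoiSample] = field(default_factory=list)


def build_phantom_case(case_id: str, seed: int, height: int = 256,
                       width: int = 256, n_plaques: int = 20,
                       axis: WavenumberAxis | None = None,
                       spectral: SpectralModel | None = None,
                       mask_cfg: MaskConfig | None = None,
                       n_folds: int = 1, n_holes: int = 1) -> PhantomCase:
    """One synthetic case: scene, rendering, slide mask, labeled ROI samples."""
    axis = axis or reduced_axis()
    spectral = spectral or SpectralModel()
    mask_cfg = mask_cfg or MaskConfig()
    cube, truth = generate_scene(height, width, n_plaques, spectral, seed=seed,
                                 n_folds=n_folds, n_holes=n_holes, axis=axis)
    ihc = render_pseudo_ihc(truth, StainParams(seed=seed + 1))
    slide_mask = ihc_to_mask(ihc, mask_cfg, pixel_size=cube.pixel_size)

    pos_positions, neg_positions = sample_positions(truth, seed=seed + 2)
    samples: list[RoiSample] = []
    dropped = 0
    from .ihc_mask import roi_label
    for r, c in pos_positions:
        # candidate amyloid windows: mask and label from the IHC pipeline;
        # windows whose stained fraction misses the 5 % rule are dropped
        window_rgb = ihc[r:r + ROI, c:c + ROI]
        window_mask = ihc_to_mask(window_rgb, mask_cfg, pixel_size=cube.pixel_size)
        y, eff, keep = roi_label(window_mask.values,
                                 mask_cfg.positive_fraction_threshold)
        if not keep or y != 1:
            dropped += 1
            continue
        samples.append(RoiSample(
            patch=np.ascontiguousarray(cube.data[r:r + ROI, c:c + ROI, :]),
            y=y, effective_mask=eff, case_id=case_id,
            sample_id=f"{case_id}:{r}:{c}", origin=(r, c)))
    for r, c in neg_positions:
        # curated amyloid-free windows: label 0 with the all-ones fallback
        samples.append(RoiSample(
            patch=np.ascontiguousarray(cube.data[r:r + ROI, c:c + ROI, :]),
            y=0, effective_mask=np.ones((ROI, ROI), dtype=np.uint8),
            case_id=case_id, sample_id=f"{case_id}:{r}:{c}", origin=(r, c)))
    if dropped:
        logger.info("case %s: dropped %d borderline window(s)", case_id, dropped)
    return PhantomCase(case_id, cube, truth, ihc, slide_mask, samples)


def build_phantom_cohort(n_cases: int = 8, seed: int = 0,
                         split_counts: tuple[int, int, int] = (4, 2, 2),
                         **case_kwargs):
    """Build ``n_cases`` cases and a case-level split specification.

    Returns ``(cases, split_spec)``; case seeds are derived deterministically
    from ``seed``.
    """
    if sum(split_counts) != n_cases:
        raise ValueError("split_counts must sum to n_cases")
    cases = [build_phantom_case(f"case{i:02d}", seed=seed * 1000 + 17 * i + 1,
                                **case_kwargs)
             for i in range(n_cases)]
    names = ["train"] * split_counts[0] + ["val"] * split_counts[1] + ["test"] * split_counts[2]
    spec = SplitSpec({c.case_id: names[i] for i, c in enumerate(cases)})
    return cases, spec


def component_hit_rate(pred_mask: np.ndarray, truth: SceneTruth,
                       min_overlap: float = 0.1) -> float:
    """Fraction of ground-truth plaque components touched by the prediction.

    A component counts as hit when at least ``min_overlap`` of its pixels
    (and at least one) are predicted positive.
    """
    n = int(truth.plaque_labels.max())
    if n == 0:
        raise ValueError("scene has no plaques")
    hits = 0
    for i in range(1, n + 1):
        comp = truth.plaque_labels == i
        ov = np.logical_and(pred_mask, comp).sum()
        if ov >= max(1, min_overlap * comp.sum()):
            hits += 1
    return hits / n


def run_weak_label_study(seed: int = 0, n_cases: int = 8,
                         n_channels: int = 16, base_width: int = 8,
                         max_epochs: int = 40,
                         eval_threshold: float = 0.5,
                         **case_kwargs) -> dict:
    """The full scaled-down study: cohort, training, selection, evaluation.

    Eight synthetic cases (256 x 256 px, compressed 16-channel band set)
    yield ~150 positive and ~150 negative ROIs under a strict 4/2/2
    case-level split; the reduced network trains for at most 40 epochs with
    the standard schedule plus a two-epoch warm-up.  Returns a dict with the
    selected epoch, held-out ROI metrics and the per-component hit rate over
    held-out slides.
    """
    axis = reduced_axis(n_channels)
    cases, split = build_phantom_cohort(n_cases=n_cases, seed=seed, axis=axis,
                                        **case_kwargs)
    samples = [s for c in cases for s in c.samples]
    train_set, val_set, test_set = split_by_case(samples, split)
    logger.info("cohort: %d train / %d val / %d test ROIs",
                len(train_set), len(val_set), len(test_set))

    cfg = TrainConfig(max_epochs=max_epochs, warmup_epochs=2,
                      early_stop_patience=10, seed=seed)
    p = TransferParams()
    model, result = train(train_set, val_set, cfg, p,
                          spec=ModelSpec(in_channels=n_channels,
                                         base_width=base_width))
    best = select_model(result.metrics_per_epoch())
    model.load_state_dict(result.history[best].state)

    test_loss, q, report = evaluate_split(model, test_set, p, result.weights)

    test_cases = [c for c in cases if split.assignment[c.case_id] == "test"]
    hit_rates = []
    for c in test_cases:
        amap = segment_wsi(model, c.cube)
        pred = binarize_activation(amap, eval_threshold, c.cube.pixel_size)
        hit_rates.append(component_hit_rate(pred.values, c.truth))
    return {
        "selected_epoch": best,
        "test_report": report,
        "test_q": q,
        "test_labels": np.array([s.y for s in test_set]),
        "hit_rate": float(np.mean(hit_rates)),
        "model": model,
        "result": result,
        "cases": cases,
        "split": split,
    }
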