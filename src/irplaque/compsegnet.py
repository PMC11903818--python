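"""Weakly supervised segmentation: masked pooling, transfer function, loss
and the training loop.

The model never sees pixel labels.  Its activation map is averaged under
the (IHC-derived) binary mask into a pooling neuron

    q = sum(a * m) / sum(m),

and a trapezoidal transfer function turns q into a class score that is 0
for q <= alpha, 1 on the plateau [alpha + ramp, alpha + beta] and decays
back to 0 beyond alpha + beta — the upper bound exists to prevent
overdetection (activating the whole mask would be penalized).  The loss is
a class-weighted cross entropy on the transferred pooling neuron plus a
background cross entropy that pushes activation to zero on masked-out
pixels of positive ROIs and on every pixel of negative ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .nn import CompSegNet, ModelSpec, RMSprop, Tensor, build_model
from .roi_dataset import RoiSample, augment
from .selection_metrics import MetricsReport, classify_roi, compute_metrics

__all__ = [
    "TransferParams", "TrainConfig", "TrainResult",
    "pooled_activation", "transfer", "loss_batch", "learning_rate", "train",
]

logger = logging.getLogger(__name__)

EPS = 1e-7


@dataclass(frozen=True)
class TransferParams:
    """Bounds of the transfer function.

    ``alpha`` is the minimum activated mask fraction expected in a positive
    ROI (5 %), ``alpha + beta`` the maximum (80 %), ``ramp`` the width of
    the linear rise and fall.
    """

    alpha: float = 0.05
    beta: float = 0.75
    ramp: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.alpha < self.alpha + self.beta <= 1.0:
            raise ValueError("require 0 < alpha < alpha + beta <= 1")
        if self.ramp <= 0:
            raise ValueError("ramp must be positive")

    @property
    def upper(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 5e-4
    decay: float = 0.9
    decay_every: int = 50
    max_epochs: int = 500
    early_stop_patience: int = 50
    batch_size: int = 20
    bg_weight: float = 1.0
    hinge_weight: float = 1.0
    #: "bce" applies the weighted cross entropy to the transferred pooling
    #: neuron (with a recovery hinge covering its flat dead zones); "hinge"
    #: replaces it with a pure margin loss on q
    class_loss: str = "bce"
    #: background activation below this floor is not penalized further,
    #: which keeps background pixels off the saturated tail of the sigmoid
    #: where all gradients vanish
    bg_floor: float = 0.05
    #: epochs of linear learning-rate warm-up damping the oversized first
    #: RMSprop steps while the squared-gradient cache fills; 0 reproduces
    #: the plain step-decay schedule
    warmup_epochs: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("lr0", "decay", "decay_every", "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Step decay: lr0 * decay ** floor(epoch / decay_every).

    During the first ``warmup_epochs`` the rate additionally ramps up
    linearly from lr0 / (warmup_epochs + 1).
    """
    lr = cfg.lr0 * cfg.decay ** (epoch // cfg.decay_every)
    if epoch < cfg.warmup_epochs:
        lr *= (epoch + 1) / (cfg.warmup_epochs + 1)
    return lr


def pooled_activation(a: np.ndarray, m: np.ndarray) -> float:
    """Masked mean of an activation map: q = sum(a*m) / sum(m)."""
    a = np.asarray(a, dtype=float)
    m = np.asarray(m, dtype=float)
    denom = m.sum()
    if denom == 0:
        raise ValueError("effective mask has no positive pixel; "
                         "the all-ones fallback should make this unreachable")
    return float((a * m).sum() / denom)


def transfer(q, p: TransferParams | None = None):
    """Trapezoidal transfer T(q): 0 below alpha, 1 on the plateau, 0 beyond."""
    p = p or TransferParams()
    q = np.asarray(q, dtype=float)
    up = np.clip((q - p.alpha) / p.ramp, 0.0, 1.0)
    down = np.clip((q - p.upper) / p.ramp, 0.0, 1.0)
    out = up - down
    return float(out) if out.ndim == 0 else out


def class_weights(y_train: np.ndarray) -> dict[int, float]:
    """w_y = N_total / (2 * N_y): balanced datasets give w0 = w1 = 1."""
    y = np.asarray(y_train)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("training labels must contain both classes")
    return {0: n / (2.0 * n0), 1: n / (2.0 * n1)}


def _batch_arrays(samples: list[RoiSample]):
    x = np.stack([s.patch for s in samples]).astype(np.float32)
    m = np.stack([s.effective_mask for s in samples]).astype(np.float32)[..., None]
    y = np.array([s.y for s in samples], dtype=np.float32)
    return x, m, y


def loss_batch(model: CompSegNet, x: np.ndarray, m: np.ndarray, y: np.ndarray,
               p: TransferParams, weights: dict[int, float],
               bg_weight: float = 1.0,
               hinge_weight: float = 1.0,
               class_loss: str = "bce",
               bg_floor: float = 0.05) -> tuple[Tensor, np.ndarray]:
    """Differentiable loss of one batch; returns (loss node, pooled q values).

    Background pixels are the mask-complement of positive ROIs plus every
    pixel of negative ROIs; their activation is pushed toward 0 through
    -log(1 - a).  The trapezoidal transfer has zero gradient outside
    [alpha, upper + ramp]; a hinge on the pooled activation of positive
    ROIs (zero inside the plateau, linear outside) keeps them recoverable
    when the background term pushes q below alpha early in training.
    """
    a = model.forward(Tensor(x))                       # (B, 64, 64, 1)
    msum = m.sum(axis=(1, 2, 3))                       # constants per sample
    q = (a * m).sum(axis=(1, 2, 3)) * (1.0 / msum)     # (B,)
    w = np.array([weights[int(v)] for v in y], dtype=np.float32)
    if class_loss == "bce":
        up = (q + (-p.alpha)) * (1.0 / p.ramp)
        down = (q + (-p.upper)) * (1.0 / p.ramp)
        t = up.clip01() + (-down.clip01())
        sample_loss = -(y * (t + EPS).log() + (1.0 - y) * ((1.0 - t) + EPS).log())
    else:
        # margin form: positives are pulled well into the plateau interior
        # (alpha + 2*ramp), negatives pushed below alpha / 2
        pos_target = min(p.alpha + 2 * p.ramp, p.upper)
        pos_term = (pos_target - q).relu() + (q - p.upper).relu()
        neg_term = (q + (-p.alpha / 2)).relu()
        sample_loss = y * pos_term + (1.0 - y) * neg_term
    class_term = (sample_loss * w).sum() * (1.0 / float(w.sum()))
    if hinge_weight > 0 and class_loss == "bce" and y.sum() > 0:
        below = ((p.alpha + p.ramp) - q).relu()
        above = (q - p.upper).relu()
        hinge = ((below + above) * y).sum() * (hinge_weight / float(max(y.sum(), 1)))
        class_term = class_term + hinge

    bg_mask = np.where(y[:, None, None, None] > 0, 1.0 - m, np.ones_like(m))
    bg_total = float(bg_mask.sum())
    if bg_total > 0:
        if bg_floor > 0:
            # margin form: no further penalty below the floor, so background
            # pixels never get driven into the flat tail of the sigmoid
            pixel_penalty = (a + (-bg_floor)).relu()
        else:
            pixel_penalty = -(((1.0 - a) + EPS).log())
        bg_term = (Tensor(bg_mask) * pixel_penalty).sum() * (1.0 / bg_total)
        total = class_term + bg_weight * bg_term
    else:
        total = class_term
    return total, q.data.copy()


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    metrics: MetricsReport
    state: dict[str, np.ndarray]


@dataclass
class TrainResult:
    history: list[EpochRecord]
    weights: dict[int, float]
    stopped_epoch: int

    def metrics_per_epoch(self) -> list[MetricsReport]:
        return [r.metrics for r in self.history]


def evaluate_split(model: CompSegNet, samples: list[RoiSample],
                   p: TransferParams, weights: dict[int, float],
                   bg_weight: float = 1.0, batch_size: int = 20,
                   hinge_weight: float = 1.0, class_loss: str = "bce",
                   bg_floor: float = 0.05):
    """Forward-only loss, pooled activations and metrics on a sample list."""
    losses, qs, ys, ns = [], [], [], []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x, m, y = _batch_arrays(chunk)
        L, q = loss_batch(model, x, m, y, p, weights, bg_weight, hinge_weight,
                          class_loss, bg_floor)
        losses.append(float(L.data) * len(chunk))
        qs.append(q)
        ys.append(y)
        ns.append(len(chunk))
    q = np.concatenate(qs)
    y = np.concatenate(ys).astype(int)
    pred = np.array([classify_roi(v, p) for v in q])
    report = compute_metrics(y, pred, q)
    return sum(losses) / sum(ns), q, report


def train(train_set: list[RoiSample], val_set: list[RoiSample],
          cfg: TrainConfig | None = None, p: TransferParams | None = None,
          spec: ModelSpec | None = None,
          model: CompSegNet | None = None) -> tuple[CompSegNet, TrainResult]:
    """Train with seeded shuffling, on-the-fly dihedral augmentation, RMSprop
    and step-decayed learning rate; checkpoints every epoch; early stopping
    on validation loss."""
    cfg = cfg or TrainConfig()
    p = p or TransferParams()
    if not train_set or not val_set:
        raise ValueError("both splits must be nonempty")
    overlap = {s.case_id for s in train_set} & {s.case_id for s in val_set}
    if overlap:
        raise ValueError(f"case leakage between train and val: {sorted(overlap)}")
    if model is None:
        spec = spec or ModelSpec(in_channels=train_set[0].patch.shape[2])
        model = build_model(spec, cfg.seed)
        model.calibrate_input(np.stack([s.patch for s in train_set[:200]]))
    weights = class_weights(np.array([s.y for s in train_set]))
    opt = RMSprop(model.parameters(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed)
    history: list[EpochRecord] = []
    best_val = np.inf
    best_epoch = -1
    for epoch in range(cfg.max_epochs):
        opt.lr = learning_rate(cfg, epoch)
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            chunk = [augment(train_set[j], int(rng.integers(0, 8))) for j in idx]
            x, m, y = _batch_arrays(chunk)
            L, _ = loss_batch(model, x, m, y, p, weights, cfg.bg_weight,
                              cfg.hinge_weight, cfg.class_loss, cfg.bg_floor)
            opt.zero_grad()
            L.backward()
            opt.step()
            epoch_loss += float(L.data) * len(chunk)
        epoch_loss /= len(order)
        val_loss, _, report = evaluate_split(model, val_set, p, weights,
                                             cfg.bg_weight, cfg.batch_size,
                                             cfg.hinge_weight, cfg.class_loss,
                                             cfg.bg_floor)
        report = replace(report, epoch=epoch)
        history.append(EpochRecord(epoch, opt.lr, epoch_loss, val_loss,
                                   report, model.state_dict()))
        logger.info("epoch %d lr %.2e train %.4f val %.4f auc %s spec %.3f",
                    epoch, opt.lr, epoch_loss, val_loss,
                    f"{report.auc_roc:.3f}" if report.auc_roc is not None else "NA",
                    report.specificity)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    return model, TrainResult(history, weights, history[-1].epoch)
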