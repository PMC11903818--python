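"""Pooling neuron, transfer function, loss and training mechanics."""

import numpy as np
import pytest

from irplaque.compsegnet import (EPS, TrainConfig, TransferParams,
                                 class_weights, learning_rate, loss_batch,
                                 pooled_activation, train, transfer)
from irplaque.nn import ModelSpec, build_model
from irplaque.roi_dataset import RoiSample


P = TransferParams()


class TestPooledActivation:
    def test_full_activation_full_mask(self):
        assert pooled_activation(np.ones((64, 64)), np.ones((64, 64))) == 1.0

    def test_zero_activation(self):
        assert pooled_activation(np.zeros((64, 64)), np.ones((64, 64))) == 0.0

    def test_activation_equal_to_mask(self):
        m = np.zeros((64, 64))
        m[10:20, 10:20] = 1
        assert pooled_activation(m, m) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pooled_activation(np.ones((4, 4)), np.zeros((4, 4)))


class TestTransfer:
    @pytest.mark.parametrize("q,expected", [
        (0.0, 0.0),
        (P.alpha, 0.0),                               # at the lower bound
        ((P.alpha + P.ramp + P.upper) / 2, 1.0),      # mid-plateau
        (1.0, 0.0),                                   # beyond upper + ramp
    ])
    def test_stated_values(self, q, expected):
        assert transfer(q, P) == pytest.approx(expected)

    def test_piecewise_structure(self):
        """T is 0 outside [alpha, upper + ramp], 1 exactly on the plateau
        [alpha + ramp, upper], and continuous piecewise-linear in between."""
        q = np.linspace(0, 1, 2001)
        t = transfer(q, P)
        assert np.all(np.abs(t[(q <= P.alpha) | (q >= P.upper + P.ramp)]) < 1e-12)
        plateau = (q >= P.alpha + P.ramp) & (q <= P.upper)
        assert np.allclose(t[plateau], 1.0)
        assert (P.upper - (P.alpha + P.ramp)) == pytest.approx(P.beta - P.ramp)
        assert np.all(np.abs(np.diff(t)) <= (q[1] - q[0]) / P.ramp + 1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TransferParams(alpha=0.5, beta=0.6)


class TestLearningRate:
    @pytest.mark.parametrize("epoch,lr", [(0, 5e-4), (50, 4.5e-4), (100, 4.05e-4)])
    def test_step_decay_schedule(self, epoch, lr):
        assert learning_rate(TrainConfig(), epoch) == pytest.approx(lr)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        assert w[0] == 1.0 and w[1] == 1.0

    def test_imbalanced(self):
        w = class_weights(np.array([1, 0, 0, 0]))
        assert w[1] == 2.0 and w[0] == pytest.approx(2 / 3)


class _FixedModel:
    """Stand-in emitting a constant activation map (for loss unit tests)."""

    def __init__(self, value):
        self.value = value

    def forward(self, x):
        from irplaque.nn import Tensor
        n = x.shape[0]
        return Tensor(np.full((n, 64, 64, 1), self.value, dtype=np.float32))


class _MaskModel:
    """Emits exactly the mask as activation (perfect positive prediction)."""

    def __init__(self, m):
        self.m = m

    def forward(self, x):
        from irplaque.nn import Tensor
        return Tensor(self.m.astype(np.float32))


class TestLoss:
    def test_ideal_prediction_near_zero(self):
        """A y=1 ROI activating half its mask (pooled q on the plateau) and a
        silent y=0 ROI produce a vanishing loss."""
        m = np.zeros((2, 64, 64, 1), dtype=np.float32)
        m[0, 10:30, 10:30, 0] = 1
        eff = np.ones_like(m)
        eff[0] = m[0]
        y = np.array([1.0, 0.0], dtype=np.float32)
        L, q = loss_batch(_MaskModel(m * 0.5), np.zeros((2, 64, 64, 3), dtype=np.float32),
                          eff, y, P, {0: 1.0, 1: 1.0})
        assert q[0] == pytest.approx(0.5) and q[1] == pytest.approx(0.0)
        assert float(L.data) < 1e-5

    def test_whole_mask_activation_is_penalized(self):
        """Activating the entire mask (q = 1, beyond the upper bound) is
        overdetection: the loss is large, not zero."""
        m = np.zeros((1, 64, 64, 1), dtype=np.float32)
        m[0, 10:30, 10:30, 0] = 1
        y = np.array([1.0], dtype=np.float32)
        L, q = loss_batch(_MaskModel(m), np.zeros((1, 64, 64, 3), dtype=np.float32),
                          m.copy(), y, P, {0: 1.0, 1: 1.0})
        assert q[0] == pytest.approx(1.0)
        assert float(L.data) > 1.0

    def test_saturated_activation_on_negative_roi(self):
        """a = 1 everywhere on a y=0 ROI drives the log background term to
        -log(eps) (the stated cross-entropy form, bg_floor = 0)."""
        eff = np.ones((1, 64, 64, 1), dtype=np.float32)
        y = np.array([0.0], dtype=np.float32)
        L, _ = loss_batch(_FixedModel(1.0), np.zeros((1, 64, 64, 3), dtype=np.float32),
                          eff, y, P, {0: 1.0, 1: 1.0}, bg_floor=0.0)
        assert float(L.data) >= -np.log(EPS) * 0.99

    def test_fifty_steps_reduce_loss_on_single_positive_roi(self, axis16):
        """Seeded gradient sanity: optimizing one positive phantom ROI for 50
        steps reduces the loss."""
        from irplaque.nn import RMSprop
        from irplaque.phantom import SpectralModel, generate_scene
        cube, truth = generate_scene(64, 64, 1, SpectralModel(), seed=9, axis=axis16)
        mask = np.zeros((1, 64, 64, 1), dtype=np.float32)
        mask[0, truth.plaque_mask, 0] = 1
        from scipy import ndimage
        mask[0, :, :, 0] = ndimage.binary_dilation(mask[0, :, :, 0],
                                                   np.ones((3, 3)), iterations=4)
        x = cube.data[None, ...]
        y = np.array([1.0], dtype=np.float32)
        model = build_model(ModelSpec(in_channels=16, base_width=2), seed=0)
        opt = RMSprop(model.parameters())
        losses = []
        for _ in range(50):
            L, _ = loss_batch(model, x, mask, y, P, {0: 1.0, 1: 1.0})
            losses.append(float(L.data))
            opt.zero_grad()
            L.backward()
            opt.step()
        assert losses[-1] < losses[0]


def _mini_dataset(axis, case_ids=("A", "B"), n=6):
    """Tiny synthetic ROI set with trivially separable labels."""
    rng = np.random.default_rng(0)
    samples = []
    for i in range(n):
        y = i % 2
        patch = rng.normal(0.5, 0.01, size=(64, 64, 4)).astype(np.float32)
        eff = np.ones((64, 64), dtype=np.uint8)
        if y:
            patch[20:40, 20:40, :] += 0.3
            eff = np.zeros((64, 64), dtype=np.uint8)
            eff[16:44, 16:44] = 1
        case = case_ids[(2 * i) // n if len(case_ids) > 1 else 0]
        samples.append(RoiSample(patch, y, eff, case, f"s{i}", (0, 0)))
    return samples


class TestTrain:
    def test_case_leakage_rejected(self):
        s = _mini_dataset(None, case_ids=("A",))
        with pytest.raises(ValueError, match="leakage"):
            train(s, s, TrainConfig(max_epochs=1),
                  spec=ModelSpec(in_channels=4, base_width=2))

    def test_one_epoch_runs_and_checkpoints(self):
        samples = _mini_dataset(None)
        tr = [s for s in samples if s.case_id == "A"]
        va = [s for s in samples if s.case_id == "B"]
        model, result = train(tr, va, TrainConfig(max_epochs=2, batch_size=3),
                              spec=ModelSpec(in_channels=4, base_width=2))
        assert len(result.history) == 2
        assert result.history[0].lr == pytest.approx(5e-4)
        expected = {str(i) for i in range(len(model.parameters()))}
        expected |= {"input_mean", "input_scale"}
        assert set(result.history[0].state) == expected

    def test_training_is_seed_deterministic(self):
        samples = _mini_dataset(None)
        tr = [s for s in samples if s.case_id == "A"]
        va = [s for s in samples if s.case_id == "B"]
        cfg = TrainConfig(max_epochs=2, batch_size=3, seed=5)
        m1, r1 = train(tr, va, cfg, spec=ModelSpec(in_channels=4, base_width=2))
        m2, r2 = train(tr, va, cfg, spec=ModelSpec(in_channels=4, base_width=2))
        assert all(np.array_equal(p.data, q.data)
                   for p, q in zip(m1.parameters(), m2.parameters()))
        assert r1.history[-1].val_loss == r2.history[-1].val_loss
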