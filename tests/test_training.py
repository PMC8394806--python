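"""Losses, the learning-rate schedule and the training loop contract."""

import math

import numpy as np
import pytest

from adenoceph.geometry import InvalidGeometryError
from adenoceph.headnet import ModelConfig, build_model
from adenoceph.synth import SynthConfig, generate_dataset
from adenoceph.training import (LossConfig, TrainConfig, _batch_total_loss,
                                coordinate_loss, geometric_loss_terms,
                                learning_rate, rotation_loss, total_loss,
                                train, translation_loss)
from adenoceph import nn

GT = np.array([[10.0, 20.0], [30.0, 40.0], [25.0, 10.0], [5.0, 15.0]])


def test_coordinate_loss_examples():
    assert coordinate_loss(GT, GT) == 0.0
    assert coordinate_loss(GT + 2.0, GT) == pytest.approx(2.0)
    off = GT.copy()
    off[0, 0] += 8.0
    assert coordinate_loss(off, GT) == pytest.approx(1.0)  # 8 / 8 components
    with pytest.raises(ValueError):
        coordinate_loss(GT[:3], GT)


def test_translation_loss_vanishes_on_the_true_line():
    gt = np.array([[0.0, 0.0], [0.0, 10.0], [5.0, 5.0], [8.0, 5.0]])
    pred = gt.copy()
    pred[0] = [0.0, -7.0]   # Ba displaced along the line
    pred[1] = [0.0, 22.0]   # Ar displaced along the line
    assert translation_loss(pred, gt) == pytest.approx(0.0, abs=1e-12)


def test_translation_loss_perpendicular_offsets():
    gt = np.array([[0.0, 0.0], [0.0, 10.0], [5.0, 5.0], [8.0, 5.0]])
    pred = gt.copy()
    pred[1] = [3.0, 10.0]   # Ar 3 px off the (vertical) line
    assert translation_loss(pred, gt) == pytest.approx(1.5)
    pred[0] = [2.0, 0.0]
    pred[1] = [2.0, 10.0]
    assert translation_loss(pred, gt) == pytest.approx(2.0)


def test_rotation_loss_examples():
    gt = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 5.0], [8.0, 5.0]])
    pred = gt + np.array([3.0, 4.0])     # rigid shift: parallel lines
    assert rotation_loss(pred, gt) == pytest.approx(0.0, abs=1e-12)
    perp = gt.copy()
    perp[1] = [0.0, 10.0]
    assert rotation_loss(perp, gt) == pytest.approx(math.pi / 2)
    diag = gt.copy()
    diag[1] = [10.0, 10.0]
    assert rotation_loss(diag, gt) == pytest.approx(math.pi / 4)
    with pytest.raises(InvalidGeometryError):
        rotation_loss(np.array([[0, 0], [0, 0], [1, 1], [2, 2]]), gt)


def test_rotation_loss_is_acute_and_order_independent(rng):
    for _ in range(50):
        pred = rng.uniform(0, 100, (4, 2))
        gt = rng.uniform(0, 100, (4, 2))
        if np.allclose(pred[0], pred[1]) or np.allclose(gt[0], gt[1]):
            continue
        th = rotation_loss(pred, gt)
        assert 0.0 <= th <= math.pi / 2 + 1e-12
        flipped = pred.copy()
        flipped[[0, 1]] = flipped[[1, 0]]
        assert rotation_loss(flipped, gt) == pytest.approx(th, abs=1e-9)


def test_geometric_loss_terms_fields():
    gt = np.array([[0.0, 0.0], [0.0, 10.0], [5.0, 5.0], [8.0, 5.0]])
    pred = gt.copy()
    pred[1] = [3.0, 10.0]
    terms = geometric_loss_terms(pred, gt)
    assert terms.Da == pytest.approx(3.0)
    assert terms.Db == pytest.approx(0.0)
    assert 0 <= terms.theta <= math.pi / 2


def test_total_loss_reductions():
    cfg = LossConfig()
    total, bd = total_loss([GT, GT], GT, cfg)
    assert total == 0.0
    plain = LossConfig(lambda_rotation=0.0, lambda_translation=0.0)
    pred = GT + 1.5
    total_plain, bd_plain = total_loss([pred, pred], GT, plain)
    assert total_plain == pytest.approx(2 * coordinate_loss(pred, GT))
    assert bd_plain["rotation"] == bd_plain["translation"] == 0.0
    # additivity over identical stacks
    one, _ = total_loss([pred], GT, cfg)
    two, _ = total_loss([pred, pred], GT, cfg)
    assert two == pytest.approx(2 * one)
    with pytest.raises(ValueError):
        total_loss([], GT, cfg)


def test_total_loss_last_stack_only_without_intermediate_supervision():
    cfg = LossConfig(intermediate_supervision=False)
    pred_bad, pred_good = GT + 10.0, GT + 1.0
    total, _ = total_loss([pred_bad, pred_good], GT, cfg)
    only_last, _ = total_loss([pred_good], GT, cfg)
    assert total == pytest.approx(only_last)


def test_batch_losses_match_reference_implementation(rng):
    """The differentiable batch path agrees with the scalar reference."""
    cfg = LossConfig()
    for _ in range(10):
        pred = rng.uniform(5, 60, (1, 4, 2))
        gt = rng.uniform(5, 60, (1, 4, 2))
        coords = nn.Tensor(pred.astype(np.float64), requires_grad=True)
        batch, _ = _batch_total_loss([coords], gt.astype(np.float64), cfg)
        ref, _ = total_loss([pred[0]], gt[0], cfg)
        assert float(batch.data) == pytest.approx(ref, rel=1e-6)


def test_learning_rate_schedule():
    cfg = TrainConfig()
    assert learning_rate(5, cfg) == pytest.approx(0.001)
    assert learning_rate(10, cfg) == pytest.approx(0.0009)
    assert learning_rate(0, cfg) == pytest.approx(0.0001)
    rates = [learning_rate(e, cfg) for e in range(5, 60)]
    assert all(b <= a for a, b in zip(rates, rates[1:]))
    assert all(r > 0 for r in rates)
    with pytest.raises(ValueError):
        learning_rate(-1, cfg)


def test_train_config_defaults_match_protocol():
    cfg = TrainConfig()
    assert cfg.batch_size == 10
    assert cfg.momentum == 0.9
    assert cfg.weight_decay == 2e-5
    assert cfg.warmup_lr == 0.001
    assert cfg.anneal_every == 5


@pytest.fixture(scope="module")
def tiny_train_setup():
    scfg = SynthConfig.scaled(32, seed=0)
    train_set = generate_dataset(scfg, 20, rng=np.random.default_rng(0))
    val_set = generate_dataset(scfg, 8, rng=np.random.default_rng(1))
    mcfg = ModelConfig(input_size=32, heatmap_size=8, n_stacks=1,
                       hourglass_depth=1, width=16)
    return train_set, val_set, mcfg


def test_train_history_bookkeeping(tiny_train_setup):
    train_set, val_set, mcfg = tiny_train_setup
    model = build_model(mcfg, seed=0)
    tcfg = TrainConfig(epochs=5, warmup_lr=0.02, warmup_epochs=2, seed=0)
    result = train(model, train_set, val_set, tcfg, LossConfig())
    assert len(result.history) == 5
    for rec in result.history:
        for key in ("train_loss", "val_localization", "val_ap", "val_ar",
                    "val_an_error"):
            assert key in rec and np.isfinite(rec[key])
    assert 0 <= result.best_epoch < 5
    # learning progress at tiny scale: the validation A/N error improves
    assert result.history[-1]["val_an_error"] < result.history[0]["val_an_error"]


def test_train_is_deterministic(tiny_train_setup):
    train_set, val_set, mcfg = tiny_train_setup
    finals = []
    for _ in range(2):
        model = build_model(mcfg, seed=3)
        tcfg = TrainConfig(epochs=2, warmup_lr=0.02, seed=3)
        result = train(model, train_set, val_set, tcfg, LossConfig())
        finals.append(result.history[-1]["train_loss"])
    assert finals[0] == pytest.approx(finals[1], abs=1e-6)


def test_train_rejects_empty_dataset(tiny_train_setup):
    _, val_set, mcfg = tiny_train_setup
    with pytest.raises(ValueError):
        train(build_model(mcfg, seed=0), [], val_set, TrainConfig(epochs=1),
              LossConfig())
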