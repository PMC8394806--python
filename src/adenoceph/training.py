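"""Losses and the training loop for the keypoint network.

The base loss is the L1 distance between predicted and ground-truth landmark
coordinates. Two geometry-prior terms encode how errors in the skull-base
line corrupt the A/N measurement:

* *translation loss* — the mean perpendicular distance of the predicted Ar
  and Ba to the ground-truth Ar–Ba line (``(Da + Db) / 2``). It vanishes for
  any prediction on the true line, however displaced along it, so it
  penalizes exactly the off-line component that shifts the A and N segments.
* *rotation loss* — the unsigned acute angle between the predicted and true
  Ar–Ba directions, which controls where the perpendicular foot of A' lands.

With intermediate supervision every hourglass stack is supervised; the plain
configuration (both prior weights zero, no attention) is the baseline arm of
the ablation.

Training uses SGD (batch 10, momentum 0.9, weight decay 2e-5) with a linear
five-epoch warm-up to the base learning rate and multiplicative annealing
every five epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .geometry import (InvalidGeometryError, LandmarkSet, Line2D,
                       point_line_distance)
from .headnet import HeadNet

__all__ = [
    "LossConfig",
    "TrainConfig",
    "GeometricLossTerms",
    "coordinate_loss",
    "translation_loss",
    "rotation_loss",
    "geometric_loss_terms",
    "total_loss",
    "learning_rate",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss composition; base coordinate loss is L1 by design."""

    base: str = "L1"
    lambda_rotation: float = 0.1
    lambda_translation: float = 0.1
    intermediate_supervision: bool = True

    def __post_init__(self) -> None:
        if self.base != "L1":
            raise ValueError("only the L1 base loss is supported")
        if self.lambda_rotation < 0 or self.lambda_translation < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule hyperparameters (study defaults)."""

    batch_size: int = 10
    momentum: float = 0.9
    weight_decay: float = 2e-5
    warmup_lr: float = 0.001
    warmup_epochs: int = 5
    anneal_every: int = 5
    anneal_factor: float = 0.9
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.warmup_epochs, self.anneal_every,
               self.epochs) <= 0:
            raise ValueError("batch_size, warmup_epochs, anneal_every, epochs "
                             "must be positive")
        if not (0 < self.anneal_factor <= 1 and self.warmup_lr > 0):
            raise ValueError("need 0 < anneal_factor <= 1 and warmup_lr > 0")


@dataclass(frozen=True)
class GeometricLossTerms:
    """Da, Db (px) and the line angle (radians) of one prediction."""

    Da: float
    Db: float
    theta: float


def _as_coords(x) -> np.ndarray:
    if isinstance(x, LandmarkSet):
        return x.as_array()
    a = np.asarray(x, dtype=float)
    if a.shape[-2:] != (4, 2):
        raise ValueError(f"expected (..., 4, 2) landmark coordinates, got {a.shape}")
    return a


def coordinate_loss(pred, gt) -> float:
    """Mean absolute difference over all coordinate components, in pixels."""
    p, g = _as_coords(pred), _as_coords(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(np.mean(np.abs(p - g)))


def translation_loss(pred, gt) -> float:
    """(Da + Db) / 2: mean distance of predicted Ar/Ba to the true line."""
    p, g = _as_coords(pred), _as_coords(gt)
    gt_lms = LandmarkSet.from_array(g)
    line = Line2D(gt_lms.Ar, gt_lms.Ba)
    pred_lms = LandmarkSet.from_array(p)
    Da = point_line_distance(pred_lms.Ar, line)
    Db = point_line_distance(pred_lms.Ba, line)
    return (Da + Db) / 2.0


def rotation_loss(pred, gt) -> float:
    """Unsigned acute angle (radians) between predicted and true Ar-Ba lines."""
    p, g = _as_coords(pred), _as_coords(gt)
    u = p[1] - p[0]  # Ba -> Ar order is (Ba, Ar, A', PNS)
    v = g[1] - g[0]
    if np.allclose(u, 0) or np.allclose(v, 0):
        raise InvalidGeometryError("degenerate Ar-Ba direction")
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = abs(float(u @ v))
    return float(math.atan2(cross, dot))


def geometric_loss_terms(pred, gt) -> GeometricLossTerms:
    p, g = _as_coords(pred), _as_coords(gt)
    gt_lms = LandmarkSet.from_array(g)
    line = Line2D(gt_lms.Ar, gt_lms.Ba)
    pred_lms = LandmarkSet.from_array(p)
    return GeometricLossTerms(
        Da=point_line_distance(pred_lms.Ar, line),
        Db=point_line_distance(pred_lms.Ba, line),
        theta=rotation_loss(p, g),
    )


def total_loss(per_stack_preds: Sequence, gt, cfg: LossConfig
               ) -> Tuple[float, Dict[str, float]]:
    """Sum of per-stack composite losses over the supervised stacks.

    With intermediate supervision all stacks contribute; otherwise only the
    last. Returns the scalar and a per-term breakdown for logging.
    """
    if len(per_stack_preds) == 0:
        raise ValueError("need at least one stack of predictions")
    stacks = per_stack_preds if cfg.intermediate_supervision else per_stack_preds[-1:]
    breakdown = {"coordinate": 0.0, "rotation": 0.0, "translation": 0.0}
    for pred in stacks:
        breakdown["coordinate"] += coordinate_loss(pred, gt)
        if cfg.lambda_rotation > 0:
            breakdown["rotation"] += cfg.lambda_rotation * rotation_loss(pred, gt)
        if cfg.lambda_translation > 0:
            breakdown["translation"] += cfg.lambda_translation * translation_loss(pred, gt)
    total = sum(breakdown.values())
    return total, breakdown


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Linear warm-up from warmup_lr/10 to warmup_lr, then stepwise annealing.

    ``learning_rate(cfg.warmup_epochs, cfg) == cfg.warmup_lr`` exactly; after
    that the rate is multiplied by ``anneal_factor`` every ``anneal_every``
    epochs.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    w = cfg.warmup_epochs
    if epoch < w:
        frac = epoch / w
        return cfg.warmup_lr * (0.1 + 0.9 * frac)
    return cfg.warmup_lr * cfg.anneal_factor ** ((epoch - w) // cfg.anneal_every)


# ---------------------------------------------------------------------------
# differentiable batch losses (heatmap-grid units)


def _batch_line_losses(coords: nn.Tensor, gt: np.ndarray,
                       ) -> Tuple[nn.Tensor, nn.Tensor]:
    """Differentiable per-batch translation and rotation losses.

    ``coords``: Tensor (N, 4, 2) predictions; ``gt``: array (N, 4, 2), both
    in the same units. Returns (translation, rotation) scalar tensors.
    """
    gBa, gAr = gt[:, 0, :], gt[:, 1, :]
    d = gAr - gBa                               # (N, 2) constant
    L = np.linalg.norm(d, axis=1)
    inv_L = (1.0 / np.maximum(L, 1e-12)).astype(gt.dtype)
    Ba, Ar = coords[:, 0, :], coords[:, 1, :]

    def line_dist(pt: nn.Tensor) -> nn.Tensor:
        # |d x (pt - gBa)| / |d|
        cross = (pt[:, 1] - gBa[:, 1]) * d[:, 0] - (pt[:, 0] - gBa[:, 0]) * d[:, 1]
        return nn.absolute(cross) * inv_L

    trans = nn.reduce_mean((line_dist(Ar) + line_dist(Ba)) * 0.5)
    ux = Ar[:, 0] - Ba[:, 0]
    uy = Ar[:, 1] - Ba[:, 1]
    dot = ux * d[:, 0] + uy * d[:, 1]
    cross = ux * d[:, 1] - uy * d[:, 0]
    rot = nn.reduce_mean(nn.arctan2(nn.absolute(cross), nn.absolute(dot)))
    return trans, rot


def _batch_total_loss(per_stack_coords: Sequence[nn.Tensor], gt: np.ndarray,
                      lcfg: LossConfig) -> Tuple[nn.Tensor, Dict[str, float]]:
    stacks = (per_stack_coords if lcfg.intermediate_supervision
              else per_stack_coords[-1:])
    terms: List[nn.Tensor] = []
    breakdown = {"coordinate": 0.0, "rotation": 0.0, "translation": 0.0}
    for coords in stacks:
        l1 = nn.reduce_mean(nn.absolute(coords - nn.Tensor(gt)))
        terms.append(l1)
        breakdown["coordinate"] += float(l1.data)
        if lcfg.lambda_translation > 0 or lcfg.lambda_rotation > 0:
            trans, rot = _batch_line_losses(coords, gt)
            if lcfg.lambda_rotation > 0:
                terms.append(rot * np.float32(lcfg.lambda_rotation))
                breakdown["rotation"] += lcfg.lambda_rotation * float(rot.data)
            if lcfg.lambda_translation > 0:
                terms.append(trans * np.float32(lcfg.lambda_translation))
                breakdown["translation"] += lcfg.lambda_translation * float(trans.data)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total, breakdown


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainResult:
    model: HeadNet
    history: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_val_an_error: float = math.inf


def _stack_images(samples) -> np.ndarray:
    return np.stack([s.image for s in samples]).astype(np.float32)


def _stack_landmarks(samples) -> np.ndarray:
    return np.stack([s.landmarks.as_array() for s in samples]).astype(np.float32)


def train(model: HeadNet, train_samples: Sequence, val_samples: Sequence,
          tcfg: TrainConfig, lcfg: LossConfig,
          log_fn=None) -> TrainResult:
    """Train a HeadNet; fully deterministic given ``tcfg.seed``.

    Per epoch the history records the train loss breakdown and validation
    localization error (input px), AP, AR and A/N ratio error. The weights
    of the epoch with the lowest validation A/N ratio error are restored
    into the model at the end.
    """
    from .evaluation import an_ratio_error, keypoint_ap_ar, localization_errors

    if len(train_samples) == 0:
        raise ValueError("empty training set")
    scale = float(model.cfg.scale)
    X = _stack_images(train_samples)
    Y = _stack_landmarks(train_samples) / scale   # heatmap units
    Xv = _stack_images(val_samples) if len(val_samples) else None
    val_gt = [s.landmarks for s in val_samples]

    rng = np.random.default_rng(tcfg.seed)
    opt = nn.SGD(model.parameters(), lr=tcfg.warmup_lr,
                 momentum=tcfg.momentum, weight_decay=tcfg.weight_decay)
    result = TrainResult(model=model)
    best_state: Optional[List[np.ndarray]] = None

    for epoch in range(tcfg.epochs):
        opt.lr = learning_rate(epoch, tcfg)
        order = rng.permutation(len(X))
        ep = {"epoch": epoch, "lr": opt.lr, "train_loss": 0.0,
              "train_coordinate": 0.0, "train_rotation": 0.0,
              "train_translation": 0.0}
        n_batches = 0
        for start in range(0, len(X), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            _, coords = model.forward(X[idx])
            loss, breakdown = _batch_total_loss(coords, Y[idx], lcfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["train_loss"] += float(loss.data)
            for k, v in breakdown.items():
                ep[f"train_{k}"] += v
            n_batches += 1
        for k in ("train_loss", "train_coordinate", "train_rotation",
                  "train_translation"):
            ep[k] /= max(n_batches, 1)

        if Xv is not None:
            preds = predict_in_batches(model, Xv, batch_size=tcfg.batch_size)
            pred_lms = [LandmarkSet.from_array(p) for p in preds]
            loc = localization_errors(pred_lms, val_gt)
            ap, ar = keypoint_ap_ar(pred_lms, val_gt)
            an = an_ratio_error(pred_lms, val_gt)
            ep.update(val_localization=loc.average, val_ap=ap, val_ar=ar,
                      val_an_error=an.mae)
            if an.mae < result.best_val_an_error:
                result.best_val_an_error = an.mae
                result.best_epoch = epoch
                best_state = [a.copy() for a in model.state_arrays()]
        result.history.append(ep)
        if log_fn is not None:
            log_fn(ep)

    if best_state is not None:
        model.load_state_arrays(best_state)
    return result


def predict_in_batches(model: HeadNet, images: np.ndarray,
                       batch_size: int = 10) -> np.ndarray:
    """Inference over an array of images; (N, 4, 2) input-space coordinates."""
    outs = [model.predict(images[i:i + batch_size])
            for i in range(0, len(images), batch_size)]
    return np.concatenate(outs, axis=0) if outs else np.zeros((0, 4, 2))
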