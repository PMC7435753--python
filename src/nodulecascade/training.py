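"""End-to-end optimisation of the cascade as a single network.

One optimizer covers the union of all three sub-networks' parameters;
the joint loss is computed on the final nodule map against the nodule
ground truth each step and back-propagated through the (softly gated)
stage boundaries.  Optional auxiliary losses supervise stage 1 against
the parenchyma mask and stage 2 against the candidate mask.

Canonical hyper-parameters: initial learning rate 0.001, batch size
40, 100 epochs, loss weights (0.9, 0.9, 0.999), weight decay 1e-4,
Adam.  Desk-scale studies shrink the batch size and epoch count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Adam, Tensor
from .losses import LossWeights, PerceptualExtractor, dice_loss, joint_loss, pixel_loss
from .networks import NoduleCascade
from .phantom import PhantomSample

__all__ = [
    "Hyperparameters",
    "TrainingHistory",
    "default_hyperparameters",
    "train",
]


@dataclass(frozen=True)
class Hyperparameters:
    learning_rate: float = 0.001
    weight_decay: float = 1e-4
    batch_size: int = 40
    epochs: int = 100
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    validation_fraction: float = 0.2
    aux_stage_weight: float = 0.0  # weight of per-stage auxiliary losses
    perceptual: str = "small"  # 'small' | 'vgg19' | 'none'
    max_grad_norm: float = 5.0  # global-norm gradient clipping; 0 disables

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


def default_hyperparameters() -> Hyperparameters:
    """The canonical full-scale training configuration."""
    return Hyperparameters()


@dataclass
class TrainingHistory:
    """Per-iteration losses and per-epoch summaries."""

    iteration_losses: list[float] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)
    validation_dice: list[float] = field(default_factory=list)
    seconds: float = 0.0

    def normalized_losses(self) -> np.ndarray:
        """Loss trajectory affinely mapped into [0, 1] for reporting."""
        arr = np.asarray(self.iteration_losses, dtype=float)
        if arr.size == 0:
            return arr
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)


def _stack(samples: list[PhantomSample], attr: str) -> np.ndarray:
    arrs = [np.asarray(getattr(s, attr), dtype=np.float32) for s in samples]
    return np.stack(arrs)[:, None]  # (N, 1, H, W)


def train(cascade: NoduleCascade, dataset: list[PhantomSample],
          hyper: Hyperparameters | None = None,
          output_dir: str | Path | None = None) -> TrainingHistory:
    """Train the cascade end-to-end on phantom samples.

    Deterministic given ``hyper.seed`` (modulo platform float behaviour).
    Raises on an empty dataset; aborts with a diagnostic on non-finite
    loss.  When ``output_dir`` is given, a checkpoint and a CSV history
    log are written per epoch.
    """
    hyper = hyper if hyper is not None else default_hyperparameters()
    if not dataset:
        raise ValueError("training dataset is empty")
    shapes = {s.image.shape for s in dataset}
    if len(shapes) != 1:
        raise ValueError("all samples must share spatial dims")
    h, w = shapes.pop()
    if h % 8 or w % 8:
        raise ValueError("sample spatial dims must be divisible by 8")

    rng = np.random.default_rng(hyper.seed)
    n_val = int(round(len(dataset) * hyper.validation_fraction))
    order = rng.permutation(len(dataset))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split left no training samples")
    train_set = [dataset[i] for i in train_idx]
    val_set = [dataset[i] for i in val_idx]

    extractor = None
    if hyper.perceptual != "none" and hyper.loss_weights.mu2 > 0:
        extractor = PerceptualExtractor(topology=hyper.perceptual,
                                        seed=hyper.seed)
    optimizer = Adam(cascade.parameters(), lr=hyper.learning_rate,
                     weight_decay=hyper.weight_decay)
    history = TrainingHistory()
    out_dir = Path(output_dir) if output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    t_start = time.time()
    cascade.train()
    for epoch in range(hyper.epochs):
        perm = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(perm), hyper.batch_size):
            batch = [train_set[i] for i in perm[start : start + hyper.batch_size]]
            images = Tensor(_stack(batch, "image"))
            gt = Tensor(_stack(batch, "nodule_mask"))
            cascade.zero_grad()
            out = cascade(images)
            loss = joint_loss(out.nodule_prob, gt, hyper.loss_weights, extractor)
            if hyper.aux_stage_weight > 0:
                gt_par = Tensor(_stack(batch, "parenchyma_mask"))
                gt_cand = Tensor(_stack(batch, "candidate_mask"))
                aux = (pixel_loss(out.parenchyma_prob, gt_par)
                       + dice_loss(out.parenchyma_prob, gt_par)
                       + pixel_loss(out.candidate_prob, gt_cand)
                       + dice_loss(out.candidate_prob, gt_cand))
                loss = loss + hyper.aux_stage_weight * aux
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss {value} at epoch {epoch}; "
                    "reduce the learning rate or check the inputs")
            loss.backward()
            if hyper.max_grad_norm > 0:
                _clip_grad_norm(cascade, hyper.max_grad_norm)
            optimizer.step()
            history.iteration_losses.append(value)
            epoch_losses.append(value)
        history.epoch_losses.append(float(np.mean(epoch_losses)))

        if val_set:
            history.validation_dice.append(_validation_dice(cascade, val_set))
            cascade.train()
        if out_dir is not None:
            np.savez(out_dir / f"checkpoint_epoch{epoch:03d}.npz",
                     **cascade.state_dict())
            _write_history_csv(out_dir / "history.csv", history)
    history.seconds = time.time() - t_start
    return history


def _clip_grad_norm(cascade: NoduleCascade, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most ``max_norm``.

    A single spiking batch can otherwise throw the shared optimizer state
    far off and stall the rest of a short training budget.
    """
    total = 0.0
    grads = [p.grad for p in cascade.parameters() if p.grad is not None]
    for g in grads:
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / (norm + 1e-12))
        for g in grads:
            g *= scale


def _validation_dice(cascade: NoduleCascade, val_set: list[PhantomSample],
                     threshold: float = 0.5) -> float:
    """Mean soft-dice complement of the final map on the validation split."""
    scores = []
    for s in val_set:
        out = cascade.predict(s.image)
        scores.append(dice_loss(out.nodule_prob,
                                s.nodule_mask.astype(np.float32)))
    return float(1.0 - np.mean(scores))


def _write_history_csv(path: Path, history: TrainingHistory) -> None:
    lines = ["epoch,mean_loss,validation_dice"]
    for i, loss in enumerate(history.epoch_losses):
        vd = history.validation_dice[i] if i < len(history.validation_dice) else ""
        lines.append(f"{i},{loss},{vd}")
    path.write_text("\n".join(lines) + "\n")
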