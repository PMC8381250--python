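"""Dice-loss training loop with plateau LR reduction and best-Dice
checkpointing.

The optimizer is stochastic gradient descent with classical momentum at
an initial learning rate of 0.01.  After each epoch the mean validation
Dice (hard masks at the configured threshold) is computed; when the
validation loss has not improved for `lr_patience` consecutive epochs
the learning rate is multiplied by `lr_factor`.  The weights from the
epoch with the highest validation Dice are returned.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .io_ct import SliceSample
from .nn import SGD, Tensor
from .postprocess import PostprocessConfig, close_volume
from .preprocess import (PreprocessConfig, geometric_augment, grayscale_float,
                         prepare_network_input)
from .snet import SNet, predict_mask


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    momentum: float = 0.9
    lr_patience: int = 3
    lr_factor: float = 0.1
    max_epochs: int = 200
    batch_size: int = 16
    loss_smooth: float = 1e-6
    seed: int = 0
    threshold: float = 0.5        # hard-mask threshold for validation Dice
    augment: bool = True
    stop_dice: float | None = None  # optional early stop on validation Dice

    def validate(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.lr_patience < 1:
            raise ValueError("lr_patience must be >= 1")
        if self.loss_smooth <= 0:
            raise ValueError("loss_smooth must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_dice": self.val_dice,
            "val_loss": self.val_loss,
            "learning_rate": self.learning_rate,
        })


def dice_loss(pred_probs: Tensor, target_mask: np.ndarray,
              smooth: float = 1e-6) -> Tensor:
    """Soft Dice loss, per sample then averaged over the batch.

    loss = 1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε) with probabilistic
    predictions p in [0,1] and binary targets t.
    """
    if not isinstance(pred_probs, Tensor):
        pred_probs = Tensor(np.asarray(pred_probs, dtype=np.float32))
    t = np.asarray(target_mask, dtype=pred_probs.data.dtype)
    if t.shape != pred_probs.data.shape:
        raise ValueError(f"shape mismatch: pred {pred_probs.data.shape} "
                         f"vs target {t.shape}")
    axes = tuple(range(1, t.ndim))
    inter = (pred_probs * Tensor(t)).sum(axis=axes)
    denom = pred_probs.sum(axis=axes) + Tensor(t.sum(axis=axes))
    return (1.0 - (2.0 * inter + smooth) / (denom + smooth)).mean()


class PlateauScheduler:
    """Reduce-on-plateau: multiply lr by `factor` after `patience`
    consecutive epochs without validation-loss improvement."""

    def __init__(self, initial_lr: float, patience: int = 3,
                 factor: float = 0.1, min_delta: float = 1e-6):
        self.lr = float(initial_lr)
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self._bad = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the lr to use next."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self._bad = 0
        else:
            self._bad += 1
            if self._bad >= self.patience:
                self.lr *= self.factor
                self._bad = 0
        return self.lr


def prepare_samples(samples: list[SliceSample],
                    config: PreprocessConfig) -> list[SliceSample]:
    """Apply the deterministic preprocessing (window, flip) to each slice."""
    out = []
    for s in samples:
        img = prepare_network_input(s.image, s.liver_mask, config)
        out.append(SliceSample(image=img, liver_mask=s.liver_mask,
                               tumor_mask=s.tumor_mask, case_id=s.case_id,
                               slice_index=s.slice_index))
    return out


def _augmented_batch(samples, idx, rng, pre_cfg: PreprocessConfig,
                     augment: bool):
    imgs, targets = [], []
    for i in idx:
        s = samples[i]
        img, tum = s.image, s.tumor_mask
        if augment:
            img, (tum,) = geometric_augment(img, [tum], rng, pre_cfg.geometric_aug)
            if pre_cfg.gray_float_enabled:
                img = grayscale_float(np.clip(img, 0, 1), rng)
        imgs.append(img)
        targets.append(tum)
    return (np.stack(imgs).astype(np.float32),
            np.stack(targets).astype(np.float32))


def _validate(model: SNet, val_samples, config: TrainConfig):
    from .nn.autograd import no_grad

    model.eval()
    losses = []
    eps = config.loss_smooth
    by_case: dict = {}
    with no_grad():
        for start in range(0, len(val_samples), config.batch_size):
            chunk = val_samples[start:start + config.batch_size]
            x = np.stack([s.image for s in chunk]).astype(np.float32)
            t = np.stack([s.tumor_mask for s in chunk]).astype(np.float32)
            probs = model(Tensor(x)).data[:, 0]
            inter = (probs * t).sum(axis=(1, 2))
            denom = probs.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
            losses.extend((1.0 - (2.0 * inter + eps) / (denom + eps)).tolist())
            for s, p in zip(chunk, probs):
                pred, ref = by_case.setdefault(s.case_id, ([], []))
                pred.append(p >= config.threshold)
                ref.append(s.tumor_mask.astype(bool))
    model.train()
    # Dice per case: each validation case's slices pooled into one volume
    case_dices = [metrics.dice(np.stack(pred), np.stack(ref))
                  for pred, ref in by_case.values()]
    return float(np.mean(case_dices)), float(np.mean(losses))


def train(model: SNet, train_samples: list[SliceSample],
          val_samples: list[SliceSample], config: TrainConfig,
          preprocess_config: PreprocessConfig | None = None,
          ) -> tuple[dict, TrainHistory]:
    """Optimize the model; return (best checkpoint state, history).

    Samples must already carry [0,1] network-input images (see
    :func:`prepare_samples`); augmentation is sampled per epoch from the
    preprocess config.
    """
    config.validate()
    if not train_samples or not val_samples:
        raise ValueError("train and validation strata must be nonempty")
    pre_cfg = preprocess_config or PreprocessConfig()
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.initial_lr, momentum=config.momentum)
    sched = PlateauScheduler(config.initial_lr, config.lr_patience, config.lr_factor)
    history = TrainHistory()
    best_dice, best_state = -1.0, None
    n = len(train_samples)

    model.train()
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, targets = _augmented_batch(train_samples, idx, rng, pre_cfg,
                                             config.augment)
            probs = model(Tensor(imgs))
            probs2d = probs.reshape(probs.data.shape[0], *probs.data.shape[2:])
            loss = dice_loss(probs2d, targets, config.loss_smooth)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={opt.lr:g})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_dice, val_loss = _validate(model, val_samples, config)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_dice.append(val_dice)
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        opt.lr = sched.step(val_loss)
        if config.stop_dice is not None and val_dice >= config.stop_dice:
            break

    checkpoint = {
        "state": best_state,
        "model_config": dataclasses.asdict(model.config),
        "preprocess_config": dataclasses.asdict(pre_cfg),
        "best_val_dice": best_dice,
        "best_epoch": history.best_epoch,
    }
    return checkpoint, history


def predict_volume(model: SNet, case, preprocess_config: PreprocessConfig,
                   postprocess_config: PostprocessConfig | None = None,
                   threshold: float = 0.5,
                   trained_preprocess: dict | None = None) -> np.ndarray:
    """Slice-wise inference on a case, restacked to 3D and closed.

    `case` needs .volume and .liver_mask (any liver mask source);
    raises if `trained_preprocess` (from a checkpoint) disagrees with
    the inference preprocessing config.
    """
    if trained_preprocess is not None:
        if trained_preprocess != dataclasses.asdict(preprocess_config):
            raise ValueError("preprocessing config differs from the one "
                             "used at training time")
    vol = case.volume
    liver = np.asarray(case.liver_mask).astype(bool)
    pred = np.zeros(vol.data.shape, dtype=bool)
    for k in range(vol.data.shape[2]):
        lv = liver[:, :, k]
        if not lv.any():
            continue
        img = prepare_network_input(vol.data[:, :, k], lv, preprocess_config)
        pred[:, :, k] = predict_mask(model, img, threshold)
        if preprocess_config.flip_enabled:
            # liver-masked input: predictions outside the liver are noise
            pred[:, :, k] &= lv
    if postprocess_config is not None:
        pred = close_volume(pred, postprocess_config)
    return pred
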