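"""Training: focal loss, augmentation, the halving learning-rate schedule, Adam.

The objective is the focal loss FL(pt) = -alpha * (1 - pt)^gamma * log(pt),
where pt is the model probability assigned to the case's true class
(pt = DLRS for label 1, 1 - DLRS for label 0). Defaults alpha = 1, gamma = 2.
The learning rate starts at 1e-3 and halves every 10 epochs; optimization is
Adam with batch size 16. Augmentation applies left/right and
anterior/posterior reflections (each with probability 0.5) and one rotation
with angle uniform in (-30, +30) degrees.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, DataError
from .nn.autodiff import Tensor
from .nn.model import HRRadNet
from .volumes import ModelInput

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FocalLossParams:
    alpha: float = 1.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma < 0:
            raise ConfigError(f"invalid focal-loss params {self}")


@dataclass(frozen=True)
class AugmentConfig:
    reflect_lr: bool = True
    reflect_ap: bool = True
    rotation_range_deg: tuple[float, float] = (-30.0, 30.0)

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not (-180 < lo <= hi < 180):
            raise ConfigError(f"rotation range must lie within (-180, 180), got {self.rotation_range_deg}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    initial_lr: float = 1e-3
    lr_halving_period: int = 10
    n_epochs: int = 30
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_halving_period) < 1 or self.initial_lr <= 0 \
                or self.n_epochs < 0:
            raise ConfigError(f"invalid training config {self}")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    val_aucs: list[float] = field(default_factory=list)
    best_epoch: int = -1


P_CLAMP = 1e-7  # numerical floor for log(pt)


def focal_loss(p, params: FocalLossParams = FocalLossParams()) -> float | np.ndarray:
    """FL(pt) = -alpha (1 - pt)^gamma log(pt) for the true-class probability pt."""
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise DataError("probabilities must lie in [0, 1]")
    pc = np.clip(p_arr, P_CLAMP, 1.0)
    out = -params.alpha * (1.0 - pc) ** params.gamma * np.log(pc)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def focal_loss_batch(probs: Tensor, labels: np.ndarray,
                     params: FocalLossParams = FocalLossParams()) -> Tensor:
    """Differentiable mean focal loss over a batch; pt = p*y + (1-p)*(1-y)."""
    y = np.asarray(labels, dtype=np.float64)
    pt = probs * y + (1.0 - probs) * (1.0 - y)
    pt = pt.clamp_min(P_CLAMP)
    per_case = -params.alpha * (1.0 - pt) ** params.gamma * pt.log()
    return per_case.mean()


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """initial_lr * 0.5 ** floor(epoch / halving_period)."""
    if epoch < 0:
        raise ConfigError("epoch index must be >= 0")
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


def _rotate_channels(channels: np.ndarray, angle: float) -> np.ndarray:
    img = ndimage.rotate(channels[0], angle, reshape=False, order=1, cval=0.0)
    msk = ndimage.rotate(channels[2], angle, reshape=False, order=0, cval=0.0)
    img = np.clip(img, 0.0, 1.0)
    msk = (msk > 0.5).astype(np.float64)
    return np.stack([img, img * msk, msk])


def augment(inp: ModelInput, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> ModelInput:
    """Random reflections (p = 0.5 each) and one rotation; mask stays binary.

    The masked-image channel is recomputed from the transformed image and mask
    so the ModelInput invariant (channel 1 = channel 0 * mask) always holds.
    """
    ch = inp.channels.copy()
    if cfg.reflect_lr and rng.random() < 0.5:
        ch = ch[:, :, ::-1]
    if cfg.reflect_ap and rng.random() < 0.5:
        ch = ch[:, ::-1, :]
    angle = float(rng.uniform(*cfg.rotation_range_deg))
    if angle != 0.0:
        ch = _rotate_channels(np.ascontiguousarray(ch), angle)
    else:
        ch = np.ascontiguousarray(ch)
    return ModelInput(channels=ch, slice_index=inp.slice_index, case_id=inp.case_id)


class Adam:
    """Adam with an externally set learning rate (the halving schedule)."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class Dataset:
    """In-memory cohort split: stacked inputs, standardized radiomics, labels."""

    images: np.ndarray  # (n, 3, S, S)
    radiomics: np.ndarray  # (n, 361), already standardized on the training split
    labels: np.ndarray  # (n,), 0/1
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.images) != n or len(self.radiomics) != n:
            raise DataError("dataset arrays disagree on n")
        if not self.case_ids:
            self.case_ids = [str(i) for i in range(n)]

    def __len__(self) -> int:
        return len(self.labels)


def _val_auc(model: HRRadNet, val: Dataset) -> float | None:
    from .evaluation import roc_auc

    if len(np.unique(val.labels)) < 2:
        return None
    scores = model.predict_proba(val.images, val.radiomics)
    return roc_auc(scores, val.labels)


def train(model: HRRadNet, train_set: Dataset, val_set: Dataset,
          cfg: TrainConfig = TrainConfig(),
          loss_params: FocalLossParams = FocalLossParams()) -> tuple[HRRadNet, TrainHistory]:
    """Epoch loop with augmentation on training cases only.

    Returns the checkpoint with the best validation AUC (last epoch if the
    validation split is single-class, with a warning). Fully reproducible for
    a fixed config seed: shuffling and augmentation consume one seeded stream.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise DataError("empty train or validation split")
    history = TrainHistory()
    if cfg.n_epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters())
    best_auc, best_state = -np.inf, None
    single_class_warned = False

    for epoch in range(cfg.n_epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_imgs = np.stack([
                augment(
                    ModelInput(train_set.images[i], slice_index=0,
                               case_id=train_set.case_ids[i]),
                    rng, cfg.augmentation,
                ).channels
                for i in idx
            ])
            probs = model.forward(
                Tensor(batch_imgs), Tensor(train_set.radiomics[idx])
            )
            loss = focal_loss_batch(probs, train_set.labels[idx], loss_params)
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            epoch_losses.append(float(loss.data))

        auc = _val_auc(model, val_set)
        history.losses.append(float(np.mean(epoch_losses)))
        history.lrs.append(lr)
        if auc is None:
            if not single_class_warned:
                warnings.warn(
                    "validation split is single-class: AUC undefined, "
                    "falling back to last-epoch checkpoint", stacklevel=2,
                )
                single_class_warned = True
            history.val_aucs.append(float("nan"))
            best_state, history.best_epoch = model.state_dict(), epoch
        else:
            history.val_aucs.append(float(auc))
            if auc > best_auc:
                best_auc, best_state, history.best_epoch = auc, model.state_dict(), epoch

    best_model = copy.deepcopy(model)
    if best_state is not None:
        best_model.load_state_dict(best_state)
    return best_model, history
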