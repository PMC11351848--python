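"""Patch assembly, BCE + soft-Dice loss, and the training schedule.

Training operates on 2D axial patches cut from the (vesselness-enhanced)
heart region of interest. Each patch is standardized to zero mean / unit
variance; slices whose mask patch is entirely empty are excluded from
training (at inference every slice is processed). The objective is the sum
of binary cross-entropy and soft-Dice terms with unit weights:

    L = w_bce * BCE(p, t) + w_dice * (1 - 2 Σpt / (Σp + Σt + ε))

Optimization follows a plateau schedule on the validation Dice score: Adam
from lr 1e-4, learning rate halved after 3 epochs without improvement,
training stopped after 5, gradient clipping at global norm 1.0, batch 16,
at most 500 epochs. An improvement means the validation DSC exceeds the
best seen so far by at least 1e-4. The train/validation split is by case,
so no case contributes patches to both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from ._layers import Adam, clip_gradients
from .preprocess import patch_standardize
from .resdense_unet import ResDenseUNet
from .volume import Mask, Volume

__all__ = [
    "TrainConfig",
    "PatchSet",
    "PlateauSchedule",
    "extract_patches",
    "bce_dice_loss",
    "train",
    "binarize",
]

EPS = 1e-7  # shared epsilon: BCE probability clipping and soft-Dice denominator


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 1e-4
    lr_factor: float = 0.5
    lr_patience: int = 3
    stop_patience: int = 5
    batch_size: int = 16
    max_epochs: int = 500
    clip_norm: float = 1.0
    loss_weights: Tuple[float, float] = (1.0, 1.0)
    threshold: float = 0.5
    train_fraction: float = 0.8
    min_delta: float = 1e-4
    epoch_multiplier: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.lr_patience < 1 or self.stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        w_bce, w_dice = self.loss_weights
        if w_bce < 0 or w_dice < 0 or (w_bce == 0 and w_dice == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.epoch_multiplier < 1:
            raise ValueError("epoch_multiplier must be >= 1")


@dataclass
class PatchSet:
    """Aligned image/mask patches with per-patch case provenance."""

    images: np.ndarray  # (N, H, W) float32, standardized
    masks: np.ndarray  # (N, H, W) uint8
    case_ids: List[str]

    def __post_init__(self) -> None:
        if self.images.shape != self.masks.shape:
            raise ValueError(
                f"image/mask patch shapes differ: {self.images.shape} vs "
                f"{self.masks.shape}"
            )
        if len(self.case_ids) != self.images.shape[0]:
            raise ValueError("one case id required per patch")

    def __len__(self) -> int:
        return self.images.shape[0]

    @staticmethod
    def concat(sets: Sequence["PatchSet"]) -> "PatchSet":
        return PatchSet(
            images=np.concatenate([s.images for s in sets], axis=0),
            masks=np.concatenate([s.masks for s in sets], axis=0),
            case_ids=[cid for s in sets for cid in s.case_ids],
        )

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            images=self.images[idx],
            masks=self.masks[idx],
            case_ids=[self.case_ids[i] for i in idx],
        )


def _fit_patch(sl: np.ndarray, size: int, fill: float = 0.0) -> np.ndarray:
    """Centre-crop and/or zero-pad a 2D slice to size x size."""
    out = np.full((size, size), fill, dtype=np.float64)
    h, w = sl.shape
    # source window (crop) and destination window (pad)
    src_y = max(0, (h - size) // 2)
    src_x = max(0, (w - size) // 2)
    dst_y = max(0, (size - h) // 2)
    dst_x = max(0, (size - w) // 2)
    ny = min(h, size)
    nx = min(w, size)
    out[dst_y : dst_y + ny, dst_x : dst_x + nx] = sl[
        src_y : src_y + ny, src_x : src_x + nx
    ]
    return out


def extract_patches(
    roi_vol: Volume,
    roi_mask: Mask | Volume,
    size: int = 256,
    case_id: str = "case",
    exclude_empty: bool = True,
) -> PatchSet:
    """One standardized patch per axial slice of the heart ROI.

    Slices are centre-cropped / zero-padded to ``size``; with
    ``exclude_empty`` (the training convention) slices whose mask patch
    contains no foreground are dropped. Raises if nothing remains.
    """
    if roi_vol.shape != roi_mask.shape:
        raise ValueError(
            f"ROI volume {roi_vol.shape} and mask {roi_mask.shape} are misaligned"
        )
    images, masks, ids = [], [], []
    for z in range(roi_vol.shape[0]):
        m = _fit_patch(np.asarray(roi_mask.data[z], float), size).astype(np.uint8)
        if exclude_empty and m.sum() == 0:
            continue
        img = patch_standardize(_fit_patch(np.asarray(roi_vol.data[z], float), size))
        images.append(img.astype(np.float32))
        masks.append(m)
        ids.append(case_id)
    if not images:
        raise ValueError(
            f"no usable patches for {case_id!r}: every slice of the mask is empty"
        )
    return PatchSet(
        images=np.stack(images), masks=np.stack(masks), case_ids=ids
    )


def bce_dice_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: Tuple[float, float] = (1.0, 1.0),
    eps: float = EPS,
) -> float:
    """Combined BCE + soft-Dice loss (weighted sum, not average).

    ``pred`` holds probabilities (clipped to [eps, 1-eps] internally);
    ``target`` is binary. Zero (up to the clipping epsilon) at a perfect
    prediction.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    w_bce, w_dice = weights
    p = np.clip(pred, eps, 1.0 - eps)
    bce = float(np.mean(-target * np.log(p) - (1.0 - target) * np.log(1.0 - p)))
    soft_dice = 2.0 * float((p * target).sum()) / (float(p.sum() + target.sum()) + eps)
    return w_bce * bce + w_dice * (1.0 - soft_dice)


def _bce_dice_grad(
    pred: np.ndarray,
    target: np.ndarray,
    weights: Tuple[float, float],
    eps: float = EPS,
) -> np.ndarray:
    """d(loss)/d(pred) for the backward pass (same clipping conventions)."""
    w_bce, w_dice = weights
    p = np.clip(pred, eps, 1.0 - eps)
    inside = (pred > eps) & (pred < 1.0 - eps)
    n = pred.size
    g_bce = np.where(inside, (-target / p + (1.0 - target) / (1.0 - p)) / n, 0.0)
    sp = float(p.sum())
    st = float(target.sum())
    spt = float((p * target).sum())
    denom = sp + st + eps
    g_dice = np.where(
        inside, -(2.0 * target * denom - 2.0 * spt) / (denom * denom), 0.0
    )
    return (w_bce * g_bce + w_dice * g_dice).astype(np.float32)


class PlateauSchedule:
    """Validation-DSC plateau tracker: LR halving and early stopping.

    ``update(dsc)`` returns ``(lr, stop)``. An epoch counts as improving
    when its DSC exceeds the best so far by at least ``min_delta``; after
    ``lr_patience`` consecutive non-improving epochs the LR is multiplied
    by ``factor`` (and the LR counter resets), after ``stop_patience`` the
    run stops.
    """

    def __init__(
        self,
        lr_init: float,
        factor: float = 0.5,
        lr_patience: int = 3,
        stop_patience: int = 5,
        min_delta: float = 1e-4,
    ):
        self.lr = lr_init
        self.factor = factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.lr_wait = 0
        self.stop_wait = 0

    def update(self, dsc: float) -> Tuple[float, bool]:
        if dsc > self.best + self.min_delta:
            self.best = dsc
            self.lr_wait = 0
            self.stop_wait = 0
            return self.lr, False
        self.lr_wait += 1
        self.stop_wait += 1
        if self.lr_wait >= self.lr_patience:
            self.lr *= self.factor
            self.lr_wait = 0
        return self.lr, self.stop_wait >= self.stop_patience


def split_by_case(
    patches: PatchSet, train_fraction: float, seed: int
) -> Tuple[PatchSet, PatchSet]:
    """Case-disjoint train/validation split (at least one case per side)."""
    cases = sorted(set(patches.case_ids))
    if len(cases) < 2:
        raise ValueError("need >= 2 cases for a case-level split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_train = int(round(train_fraction * len(cases)))
    n_train = min(max(n_train, 1), len(cases) - 1)
    train_cases = {cases[i] for i in order[:n_train]}
    ids = np.asarray(patches.case_ids)
    train_idx = np.flatnonzero(np.isin(ids, sorted(train_cases)))
    val_idx = np.flatnonzero(~np.isin(ids, sorted(train_cases)))
    return patches.subset(train_idx), patches.subset(val_idx)


@dataclass
class TrainResult:
    history: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -np.inf
    grad_norms: List[float] = field(default_factory=list)


def _validation_dsc(
    model: ResDenseUNet, images: np.ndarray, masks: np.ndarray, threshold: float,
    batch_size: int,
) -> float:
    """Pooled Dice over all validation patches at the given threshold."""
    tp = fp = fn = 0
    for start in range(0, images.shape[0], batch_size):
        x = images[start : start + batch_size, None]
        prob = model.forward(x, train=False)[:, 0]
        pred = prob > threshold
        t = masks[start : start + batch_size].astype(bool)
        tp += int(np.count_nonzero(pred & t))
        fp += int(np.count_nonzero(pred & ~t))
        fn += int(np.count_nonzero(~pred & t))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _snapshot(model: ResDenseUNet) -> List[np.ndarray]:
    arrays = [p.copy() for p in model.params()]
    for bn in model._bn_layers():
        arrays.append(bn.running_mean.copy())
        arrays.append(bn.running_var.copy())
    return arrays


def _restore(model: ResDenseUNet, snap: List[np.ndarray]) -> None:
    n = len(model.params())
    for p, s in zip(model.params(), snap[:n]):
        p[...] = s
    rest = snap[n:]
    for i, bn in enumerate(model._bn_layers()):
        bn.running_mean[...] = rest[2 * i]
        bn.running_var[...] = rest[2 * i + 1]


def train(
    model: ResDenseUNet,
    patches: PatchSet,
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Optimize the model on a PatchSet; returns history + best weights.

    The split is case-disjoint; the model is left holding the weights of
    the best-validation-DSC epoch. ``TrainResult.grad_norms`` records the
    post-clip global gradient norm of every step.
    """
    cfg = cfg or TrainConfig()
    train_set, val_set = split_by_case(patches, cfg.train_fraction, cfg.seed)
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty train or validation split")

    # start the head at the foreground prior: with sparse targets a zero
    # bias wastes the first epochs unlearning a 50% foreground assumption
    prior = float(np.clip(train_set.masks.mean(), 1e-4, 1.0 - 1e-4))
    model.head.b[...] = np.log(prior / (1.0 - prior))

    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = Adam(model.params(), lr=cfg.lr_init)
    schedule = PlateauSchedule(
        cfg.lr_init,
        cfg.lr_factor,
        cfg.lr_patience,
        cfg.stop_patience,
        cfg.min_delta,
    )
    result = TrainResult()
    best_snap = None

    for epoch in range(cfg.max_epochs):
        # an "epoch" may replicate the (reshuffled) patch set: on small
        # synthetic sets this keeps optimizer steps per epoch comparable
        # to a full-size training corpus without touching lr/batch/clip
        order = np.concatenate(
            [rng.permutation(len(train_set)) for _ in range(cfg.epoch_multiplier)]
        )
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = train_set.images[idx][:, None]
            t = train_set.masks[idx][:, None].astype(np.float32)
            prob = model.forward(x, train=True)
            losses.append(bce_dice_loss(prob, t, cfg.loss_weights))
            model.backward(_bce_dice_grad(prob, t, cfg.loss_weights))
            grads = model.grads()
            norm = clip_gradients(grads, cfg.clip_norm)
            result.grad_norms.append(norm)
            optimizer.lr = schedule.lr
            optimizer.step(grads)

        val_dsc = _validation_dsc(
            model, val_set.images, val_set.masks, cfg.threshold, cfg.batch_size
        )
        lr_used = schedule.lr
        if val_dsc > result.best_val_dsc:
            result.best_val_dsc = val_dsc
            result.best_epoch = epoch
            best_snap = _snapshot(model)
        _, stop = schedule.update(val_dsc)
        result.history.append(
            {
                "epoch": epoch,
                "lr": lr_used,
                "train_loss": float(np.mean(losses)),
                "val_dsc": val_dsc,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr_used:.2e} "
                f"loss {np.mean(losses):.4f} val_dsc {val_dsc:.4f}"
            )
        if stop:
            break

    if best_snap is not None:
        _restore(model, best_snap)
    return result


def binarize(prob, threshold: float = 0.5):
    """Strict thresholding: mask = 1 where probability > threshold.

    Accepts a Volume (returns a Mask with the same metadata) or a bare
    array (returns a uint8 array). Idempotent: re-binarizing a binary map
    leaves it unchanged for any threshold in (0, 1).
    """
    if isinstance(prob, Volume):
        data = np.asarray(prob.data, dtype=np.float64)
        return Mask(
            data=(data > threshold).astype(np.uint8),
            spacing=prob.spacing,
            origin=prob.origin,
            direction=prob.direction,
        )
    return (np.asarray(prob, dtype=np.float64) > threshold).astype(np.uint8)
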