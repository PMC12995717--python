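"""Training protocol: patient-level splits, sweeps, scheduler, loop.

The protocol mirrors standard clinical-ML practice: data are split
70/15/15 into train/development/test **by patient** so no patient leaks
across partitions; hyperparameters are drawn from a fixed sweep
distribution (log-uniform learning rate on [1e-6, 5e-2], plateau
patience from {3, 5, 7, 10}, decay factor from {0.3, 0.5, 0.7});
optimization is SGD (momentum 0.9, weight decay 1e-4) with
reduce-on-plateau learning-rate decay monitoring development loss at a
5% threshold; every epoch is checkpointed and the final model is the
checkpoint with the highest development AUC (task models) or the lowest
development loss (view/doppler classifiers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform
from sklearn.metrics import roc_auc_score

from . import nn
from .errors import ConfigurationError, TrainingDivergedError

logger = logging.getLogger(__name__)

LR_RANGE = (1e-6, 5e-2)
PATIENCE_CHOICES = (3, 5, 7, 10)
FACTOR_CHOICES = (0.3, 0.5, 0.7)
TRAIN_MODES = ("single_view", "multiview", "view_classifier", "doppler")


@dataclass(frozen=True)
class HyperParams:
    learning_rate: float = 0.01
    scheduler_patience: int = 5
    scheduler_factor: float = 0.5
    scheduler_threshold: float = 0.05
    scheduler_threshold_mode: str = "rel"   # {"rel", "abs"}
    epochs: int = 50
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]):
            raise ConfigurationError(
                f"learning rate {self.learning_rate} outside {LR_RANGE}")
        if self.scheduler_patience not in PATIENCE_CHOICES:
            raise ConfigurationError(
                f"patience must be one of {PATIENCE_CHOICES}")
        if self.scheduler_factor not in FACTOR_CHOICES:
            raise ConfigurationError(f"factor must be one of {FACTOR_CHOICES}")


def view_classifier_hyperparams(**overrides) -> HyperParams:
    """The view/doppler classifier recipe: lr 0.01, factor 0.5, patience
    50, absolute loss threshold 0.01, 1,000 epochs (selection by lowest
    development loss)."""
    patience = overrides.pop("scheduler_patience", 50)
    hp = HyperParams(learning_rate=0.01, scheduler_factor=0.5,
                     scheduler_threshold=0.01, scheduler_threshold_mode="abs",
                     epochs=1000)
    hp = replace(hp, **overrides)
    # patience 50 sits outside the sweep's finite set, so bypass validation
    object.__setattr__(hp, "scheduler_patience", patience)
    return hp


@dataclass(frozen=True)
class AugmentParams:
    crop_scale_range: tuple[float, float] = (0.95, 1.0)
    color_jitter_range: tuple[float, float] = (0.8, 1.2)
    rotation_range_deg: tuple[float, float] = (-5.0, 5.0)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]           # patient_id -> partition
    ratios: tuple[float, float, float]
    seed: int

    def partition_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients(self, partition: str) -> list[str]:
        return [p for p, part in self.assignment.items() if part == partition]


@dataclass
class TrainRecord:
    entries: list[dict] = field(default_factory=list)
    checkpoints: list[dict] = field(default_factory=list)   # state dicts
    mode: str = "single_view"
    determinism: str = "numpy-deterministic (single-threaded BLAS excepted)"


@dataclass
class Checkpoint:
    epoch: int                 # 1-based
    state: dict
    dev_auc: float
    dev_loss: float


PARTITIONS = ("train", "dev", "test")


def split_by_patient(manifest: pd.DataFrame,
                     ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0) -> SplitAssignment:
    """Shuffle patients with ``seed`` and assign to hit the ratios as
    closely as integer counts allow (largest-remainder rounding)."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    shuffled = [patients[i] for i in order]
    n = len(patients)
    exact = np.array(ratios) * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[:n - counts.sum()]:
        counts[i] += 1
    assignment = {}
    start = 0
    for part, cnt in zip(PARTITIONS, counts):
        for p in shuffled[start:start + cnt]:
            assignment[p] = part
        start += cnt
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios),
                           seed=seed)


def check_no_leakage(manifest: pd.DataFrame, split: SplitAssignment) -> int:
    """Number of patients whose studies span more than one partition
    (must be zero by construction; re-checked on every run)."""
    parts = manifest["patient_id"].map(split.assignment)
    leaks = manifest.assign(_part=parts).groupby("patient_id")["_part"].nunique()
    return int((leaks > 1).sum())


def filter_complete_studies(manifest: pd.DataFrame, required_views,
                            doppler_required: bool = False,
                            return_stats: bool = False):
    """Keep studies with >= 1 video for every required (view, doppler)
    combination; among multiple candidates, first by path sort order."""
    required_views = list(required_views)
    if not required_views:
        raise ValueError("required_views must be non-empty")
    sub = manifest[(manifest["view"].isin(required_views))
                   & (manifest["doppler"] == doppler_required)]
    sub = sub.sort_values("path").drop_duplicates(["study_id", "view"])
    counts = sub.groupby("study_id")["view"].nunique()
    complete = counts[counts == len(required_views)].index
    out = sub[sub["study_id"].isin(complete)].sort_values(
        ["study_id", "view"]).reset_index(drop=True)
    n_total = manifest["study_id"].nunique()
    n_kept = out["study_id"].nunique()
    excluded_fraction = 1.0 - n_kept / n_total if n_total else 0.0
    logger.info("filter_complete_studies: kept %d/%d studies (%.1f%% excluded)",
                n_kept, n_total, 100 * excluded_fraction)
    if return_stats:
        return out, excluded_fraction
    return out


def sample_hyperparams(n_trials: int = 40, seed: int = 0,
                       **fixed) -> list[HyperParams]:
    """Sweep trials: log-uniform learning rate, patience/factor uniform
    over their finite sets; deterministic given ``seed``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(LR_RANGE[0]), np.log10(LR_RANGE[1])
    trials = []
    for i in range(n_trials):
        lr = float(10.0 ** rng.uniform(lo, hi))
        patience = int(rng.choice(PATIENCE_CHOICES))
        factor = float(rng.choice(FACTOR_CHOICES))
        trials.append(HyperParams(learning_rate=lr, scheduler_patience=patience,
                                  scheduler_factor=factor,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  **fixed))
    return trials


class PlateauScheduler:
    """Reduce-on-plateau: decay the learning rate by ``factor`` once the
    monitored loss has failed to improve beyond ``threshold`` for more
    than ``patience`` consecutive epochs; each decay resets the counter."""

    def __init__(self, lr: float, factor: float, patience: int,
                 threshold: float = 0.05, threshold_mode: str = "rel"):
        self.lr = float(lr)
        self.factor = float(factor)
        self.patience = int(patience)
        self.threshold = float(threshold)
        if threshold_mode not in ("rel", "abs"):
            raise ConfigurationError("threshold_mode must be 'rel' or 'abs'")
        self.threshold_mode = threshold_mode
        self.best = np.inf
        self.num_bad = 0

    def _improved(self, loss: float) -> bool:
        if self.threshold_mode == "rel":
            return loss < self.best * (1.0 - self.threshold)
        return loss < self.best - self.threshold

    def step(self, loss: float) -> float:
        if self._improved(loss):
            self.best = loss
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.lr *= self.factor
                self.num_bad = 0
        return self.lr


def plateau_lr_step(current_lr: float, loss_history, hp: HyperParams) -> float:
    """Replay the plateau rule over a full loss history; returns the
    learning rate in force after the last epoch."""
    if len(loss_history) == 0:
        raise ValueError("loss_history must be non-empty")
    sched = PlateauScheduler(current_lr, hp.scheduler_factor,
                             hp.scheduler_patience, hp.scheduler_threshold,
                             hp.scheduler_threshold_mode)
    for loss in loss_history:
        lr = sched.step(float(loss))
    return lr


def augment_clip(clip, params: AugmentParams, rng: np.random.Generator,
                 return_params: bool = False):
    """One crop-scale/jitter/rotation draw per clip, applied identically
    to every frame (temporal consistency). Identity draws are bit-exact
    no-ops."""
    frames = clip.frames if hasattr(clip, "frames") else np.asarray(clip)
    t_n, s = frames.shape[0], frames.shape[1]
    scale = float(rng.uniform(*params.crop_scale_range))
    jitter = float(rng.uniform(*params.color_jitter_range))
    angle = float(rng.uniform(*params.rotation_range_deg))
    out = frames
    crop = int(round(s * scale))
    if crop != s:
        max_off = s - crop
        r0 = int(rng.integers(0, max_off + 1))
        c0 = int(rng.integers(0, max_off + 1))
        cropped = out[:, r0:r0 + crop, c0:c0 + crop].astype(np.float64)
        out = np.stack([transform.resize(f, (s, s, 3), order=1,
                                         preserve_range=True,
                                         anti_aliasing=False)
                        for f in cropped])
    if angle != 0.0:
        out = ndimage.rotate(out.astype(np.float64), angle, axes=(1, 2),
                             reshape=False, order=1)
    if jitter != 1.0:
        out = out.astype(np.float64) * jitter
    if out is not frames:
        out = np.clip(np.rint(out), 0, 255).astype(frames.dtype)
    draw = {"crop_scale": scale, "color_jitter": jitter, "rotation_deg": angle}
    if return_params:
        return out, draw
    return out


# ---------------------------------------------------------------------------
# datasets + loop


@dataclass
class ClipDataset:
    """In-memory single-view dataset: (N, T, H, W, 3) uint8 + labels."""

    clips: np.ndarray
    labels: np.ndarray

    def __len__(self):
        return len(self.labels)


@dataclass
class MultiviewDataset:
    """view name -> (N, T, H, W, 3) uint8, aligned with labels."""

    clips: dict[str, np.ndarray]
    labels: np.ndarray

    def __len__(self):
        return len(self.labels)


def to_model_input(batch: np.ndarray) -> np.ndarray:
    """(B, T, H, W, 3) uint8 -> (B, 3, T, H, W) float32 in [0, 1]."""
    return np.ascontiguousarray(
        batch.transpose(0, 4, 1, 2, 3)).astype(np.float32) / 255.0


def _forward_loss(model, batch_clips, labels, mode, train: bool):
    if mode == "multiview":
        logits = model.forward_logits([to_model_input(c) for c in batch_clips])
    else:
        logits = model.forward_logits(to_model_input(batch_clips))
    if mode == "view_classifier":
        loss, grad = nn.cross_entropy(logits, labels)
    else:
        loss, grad = nn.bce_with_logits(logits[:, 0], labels)
        grad = grad[:, None]
    return logits, loss, grad


def _dev_metrics(model, dev_set, mode, batch_size):
    model.eval()
    logits_all, labels = [], dev_set.labels
    n = len(dev_set)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        if mode == "multiview":
            batch = [dev_set.clips[v][sl] for v in dev_set.clips]
            logits = model.forward_logits([to_model_input(c) for c in batch])
        else:
            logits = model.forward_logits(to_model_input(dev_set.clips[sl]))
        logits_all.append(logits)
    logits = np.concatenate(logits_all, axis=0)
    if mode == "view_classifier":
        loss, _ = nn.cross_entropy(logits, labels)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        try:   # mean one-vs-rest AUC per class
            auc = float(np.mean([
                roc_auc_score((labels == k).astype(int), probs[:, k])
                for k in range(probs.shape[1]) if len(set(labels == k)) > 1]))
        except ValueError:
            auc = float("nan")
        scores = probs
    else:
        loss, _ = nn.bce_with_logits(logits[:, 0], labels)
        scores = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        try:
            auc = float(roc_auc_score(labels, scores))
        except ValueError:
            auc = float("nan")
    model.train()
    return loss, auc, scores


def predict_scores(model, dataset, mode: str = "single_view",
                   batch_size: int = 32) -> np.ndarray:
    """Scores on a dataset with the model in eval mode."""
    _, _, scores = _dev_metrics(model, dataset, mode, batch_size)
    return scores


def train(model, train_set, dev_set, hp: HyperParams,
          augment: AugmentParams | None = None, mode: str = "single_view",
          verbose: bool = False) -> TrainRecord:
    """Full-epoch SGD loop with per-epoch checkpoints and logging.

    Deterministic given ``hp.seed`` (numpy compute; BLAS threading is
    the only backend caveat, recorded on the TrainRecord).
    """
    if mode not in TRAIN_MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng([hp.seed, 17])
    opt = nn.SGD(model.parameters(), lr=hp.learning_rate,
                 momentum=hp.momentum, weight_decay=hp.weight_decay)
    sched = PlateauScheduler(hp.learning_rate, hp.scheduler_factor,
                             hp.scheduler_patience, hp.scheduler_threshold,
                             hp.scheduler_threshold_mode)
    record = TrainRecord(mode=mode)
    n = len(train_set)
    model.train()
    for epoch in range(1, hp.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            labels = train_set.labels[idx]
            if mode == "multiview":
                batch = [train_set.clips[v][idx] for v in train_set.clips]
                if augment is not None:
                    batch = [np.stack([augment_clip(c, augment, rng)
                                       for c in view_batch])
                             for view_batch in batch]
            else:
                batch = train_set.clips[idx]
                if augment is not None:
                    batch = np.stack([augment_clip(c, augment, rng)
                                      for c in batch])
            opt.zero_grad()
            _, loss, grad = _forward_loss(model, batch, labels, mode, True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={opt.lr:.3g})")
            model.backward_logits(grad)
            opt.step()
            losses.append(loss)
        dev_loss, dev_auc, _ = _dev_metrics(model, dev_set, mode, hp.batch_size)
        record.entries.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "dev_loss": float(dev_loss), "dev_auc": float(dev_auc),
            "lr": opt.lr,
        })
        record.checkpoints.append(model.state_dict())
        opt.lr = sched.step(dev_loss)
        if verbose:
            logger.info("epoch %d: train %.4f dev %.4f auc %.4f lr %.2g",
                        epoch, record.entries[-1]["train_loss"], dev_loss,
                        dev_auc, opt.lr)
    model.eval()
    return record


def select_checkpoint(record: TrainRecord,
                      criterion: str = "max_dev_auc") -> Checkpoint:
    """Best epoch by dev AUC (task models) or dev loss (view/doppler
    classifiers); ties break toward the earliest epoch."""
    if not record.entries:
        raise ValueError("empty training record")
    if criterion == "max_dev_auc":
        values = [e["dev_auc"] for e in record.entries]
        best = int(np.argmax(values))      # argmax returns first maximum
    elif criterion == "min_dev_loss":
        values = [e["dev_loss"] for e in record.entries]
        best = int(np.argmin(values))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    entry = record.entries[best]
    return Checkpoint(epoch=entry["epoch"], state=record.checkpoints[best],
                      dev_auc=entry["dev_auc"], dev_loss=entry["dev_loss"])
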