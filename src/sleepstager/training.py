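"""Subject-disjoint cross-validation training protocol.

Recordings are partitioned by subject into k folds (default 5), so no
individual contributes epochs to both the training and test side of any
fold.  Within each fold, 10% of the training epochs are held out (stratified
by class — N1 is too rare for an unstratified holdout to be stable) to drive
early stopping: training runs Adam at learning rate 0.001 with batch size 64
for at most 100 epochs and stops once the validation loss has not improved
for 5 consecutive epochs, restoring the parameters of the best epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import ConfusionMatrix, confusion
from .model import (ModelConfig, SleepStageNet, build_variant,
                    cross_entropy_loss, inverse_frequency_weights)
from .nn import DTYPE, Adam
from .preprocess import SleepEpochSet

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Assignment of subjects to k disjoint test folds."""

    folds: list[tuple[list[str], list[str]]]  # (train subjects, test subjects)
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def validate(self):
        all_test: list[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("subject appears in both train and test")
            all_test.extend(test)
        if len(all_test) != len(set(all_test)):
            raise ValueError("a subject appears in more than one test fold")
        return self


@dataclass
class TrainConfig:
    """Optimization protocol parameters."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    val_fraction: float = 0.10
    class_weights: bool = False
    seed: int = 0


@dataclass
class TrainLog:
    records: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.records.append(dict(kw))

    def best_val_loss(self) -> float:
        return min(r["loss"] for r in self.records if r["split"] == "val")


class NonFiniteLossError(RuntimeError):
    pass


def make_subject_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random balanced partition of subjects into k test folds.

    Fold sizes differ by at most one subject; all of a subject's recordings
    travel together because the split is at subject level.
    """
    subjects = sorted(set(map(str, subject_ids)))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, "
                         f"got {len(subjects)}")
    order = np.random.default_rng(seed).permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    folds = []
    bounds = np.linspace(0, len(subjects), k + 1).round().astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        test = shuffled[lo:hi]
        train = [s for s in shuffled if s not in test]
        folds.append((train, test))
    return FoldPlan(folds, seed).validate()


def split_validation(n: int, labels: np.ndarray, fraction: float = 0.10,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified epoch-level holdout: returns (train_idx, val_idx).

    The holdout has round(fraction * n) epochs overall, drawn proportionally
    from each class so rare stages are represented.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_val = int(round(fraction * n))
    labels = np.asarray(labels)
    val_parts = []
    classes = np.unique(labels)
    # proportional per-class counts, largest-remainder rounding to hit n_val
    quotas = np.array([fraction * (labels == c).sum() for c in classes])
    take = np.floor(quotas).astype(int)
    rem = n_val - take.sum()
    if rem > 0:
        order = np.argsort(-(quotas - take))
        take[order[:rem]] += 1
    for c, t in zip(classes, take):
        idx = np.flatnonzero(labels == c)
        val_parts.append(rng.permutation(idx)[:t])
    val_idx = np.sort(np.concatenate(val_parts))
    mask = np.ones(n, dtype=bool)
    mask[val_idx] = False
    return np.flatnonzero(mask), val_idx


def _evaluate(model: SleepStageNet, x: np.ndarray, y: np.ndarray,
              class_weights: np.ndarray | None,
              batch_size: int = 256) -> tuple[float, float]:
    """(mean loss, accuracy) in evaluation mode."""
    model.eval()
    losses, hits, n = [], 0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.forward(xb)
        loss = cross_entropy_loss(logits, yb, class_weights)
        losses.append(float(loss.data) * len(xb))
        hits += int((logits.data.argmax(axis=1) == yb).sum())
        n += len(xb)
    model.train()
    return sum(losses) / n, hits / n


def fit(model: SleepStageNet, train_set: SleepEpochSet,
        val_set: SleepEpochSet, config: TrainConfig | None = None,
        ) -> TrainLog:
    """Train with early stopping on validation loss; restores best weights."""
    cfg = config or TrainConfig()
    x_tr = train_set.signals.astype(DTYPE)
    y_tr = train_set.labels
    x_va = val_set.signals.astype(DTYPE)
    y_va = val_set.labels
    weights = (inverse_frequency_weights(y_tr) if cfg.class_weights else None)

    optimizer = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    log = TrainLog()
    best_loss = np.inf
    best_state = None
    since_best = 0
    model.train()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_tr))  # fresh shuffle every epoch
        epoch_loss, hits = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            model.zero_grad()
            logits = model.forward(xb)
            loss = cross_entropy_loss(logits, yb, weights)
            if not np.isfinite(loss.data):
                raise NonFiniteLossError(
                    f"non-finite loss in epoch {epoch}, batch "
                    f"{start // cfg.batch_size}")
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
            hits += int((logits.data.argmax(axis=1) == yb).sum())
        log.append(epoch=epoch, split="train",
                   loss=epoch_loss / len(order), accuracy=hits / len(order))

        val_loss, val_acc = _evaluate(model, x_va, y_va, weights)
        log.append(epoch=epoch, split="val", loss=val_loss, accuracy=val_acc)
        logger.info("epoch %d train_loss=%.4f val_loss=%.4f val_acc=%.3f",
                    epoch, epoch_loss / len(order), val_loss, val_acc)

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (patience %d)",
                            epoch, cfg.patience)
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return log


@dataclass
class CrossValidationResult:
    plan: FoldPlan
    predictions: np.ndarray       # one test-time prediction per epoch
    fold_confusions: list[ConfusionMatrix]
    logs: list[TrainLog]

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        total = sum((c.counts for c in self.fold_confusions),
                    np.zeros((5, 5), dtype=np.int64))
        return ConfusionMatrix(total)


def check_no_leakage(plan: FoldPlan, dataset: SleepEpochSet):
    """Audit: no subject may sit on both sides of any fold."""
    subjects = set(map(str, dataset.subject_ids))
    for i, (train, test) in enumerate(plan.folds):
        overlap = set(train) & set(test)
        if overlap:
            raise ValueError(f"fold {i}: subjects in train and test: "
                             f"{sorted(overlap)}")
        unknown = (set(train) | set(test)) - subjects
        if unknown:
            raise ValueError(f"fold {i}: unknown subjects {sorted(unknown)}")


def run_cross_validation(dataset: SleepEpochSet,
                         model_config: ModelConfig | None = None,
                         variant: str = "full",
                         train_config: TrainConfig | None = None,
                         k: int = 5,
                         plan: FoldPlan | None = None,
                         ) -> CrossValidationResult:
    """Subject-disjoint k-fold cross-validation of one model variant.

    Every epoch receives exactly one test-time prediction (from the fold
    whose test side holds its subject); the pooled confusion matrix is the
    elementwise sum over folds.
    """
    cfg = train_config or TrainConfig()
    mcfg = model_config or ModelConfig()
    if plan is None:
        plan = make_subject_folds(dataset.subject_ids, k=k, seed=cfg.seed)
    check_no_leakage(plan, dataset)

    subj = dataset.subject_ids.astype(str)
    predictions = np.full(len(dataset), -1, dtype=np.int64)
    fold_confusions, logs = [], []
    n_input = 2 if variant == "eeg_only" else 4

    for i, (train_subjects, test_subjects) in enumerate(plan.folds):
        tr_mask = np.isin(subj, train_subjects)
        te_mask = np.isin(subj, test_subjects)
        train_all = dataset.select(np.flatnonzero(tr_mask))
        tr_idx, va_idx = split_validation(
            len(train_all), train_all.labels, cfg.val_fraction,
            seed=cfg.seed + i)
        model = build_variant(
            variant, ModelConfig(**{**mcfg.to_dict(),
                                    "seed": mcfg.seed + i}))
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 100 + i})
        train_sub = channel_view(train_all.select(tr_idx), n_input)
        val_sub = channel_view(train_all.select(va_idx), n_input)
        logs.append(fit(model, train_sub, val_sub, fold_cfg))

        te_idx = np.flatnonzero(te_mask)
        x_te = dataset.signals[te_idx][:, :n_input, :].astype(DTYPE)
        preds = model.predict(x_te)
        predictions[te_idx] = preds
        fold_confusions.append(confusion(dataset.labels[te_idx], preds))

    if (predictions < 0).any():
        raise RuntimeError("some epochs received no test-time prediction")
    return CrossValidationResult(plan, predictions, fold_confusions, logs)


def channel_view(epochs: SleepEpochSet, n_channels: int) -> SleepEpochSet:
    """View of the first ``n_channels`` input channels (e.g. the two EEG
    derivations for the EEG-only variant); shares the underlying arrays."""
    if n_channels == epochs.signals.shape[1]:
        return epochs
    out = object.__new__(SleepEpochSet)
    out.signals = epochs.signals[:, :n_channels, :]
    out.labels = epochs.labels
    out.subject_ids = epochs.subject_ids
    out.recording_ids = epochs.recording_ids
    return out
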