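"""From recordings + annotations to labeled 30 s epochs.

The scored labels follow the Sleep-EDF dialect of the older R&K standard;
they are mapped to the five AASM classes (W, N1, N2, N3, REM), with R&K
stages 3 and 4 merged into N3 as is universal practice.  "Movement time" and
unscored ("Sleep stage ?") slots are excluded.  Long wake stretches before
sleep onset and after final offset are trimmed to a configurable margin
(default 30 min), the convention behind published epoch counts on this
dataset.  Signals are z-scored per recording and channel, since raw EDF
channels differ in physical scale by orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .edf_io import EPOCH_SEC, TARGET_RATE, AnnotationTrack, TimeSeriesRecording

logger = logging.getLogger(__name__)

N_CLASSES = 5
N_CHANNELS = 4
SAMPLES_PER_EPOCH = int(EPOCH_SEC * TARGET_RATE)  # 3000

STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")

#: scored-label vocabulary -> class index; EXCLUDED marks dropped slots
EXCLUDED = -1
LABEL_MAP = {
    "Sleep stage W": 0,
    "Sleep stage 1": 1,
    "Sleep stage 2": 2,
    "Sleep stage 3": 3,
    "Sleep stage 4": 3,  # R&K stage 4 merges into N3
    "Sleep stage R": 4,
    "Sleep stage ?": EXCLUDED,
    "Movement time": EXCLUDED,
}

CHANNEL_ORDER = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG", "EMG")


class UnknownStageLabelError(ValueError):
    pass


@dataclass
class SleepEpochSet:
    """Labeled 30 s epochs: the unit of classification.

    ``signals`` has shape (n_epochs, 4, 3000): four channels at 100 Hz in the
    fixed order EEG Fpz-Cz, EEG Pz-Oz, EOG, EMG.  ``labels`` are the five
    AASM classes 0:W 1:N1 2:N2 3:N3 4:REM.
    """

    signals: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    recording_ids: np.ndarray

    def __post_init__(self):
        self.signals = np.asarray(self.signals)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.recording_ids = np.asarray(self.recording_ids, dtype=object)
        n = len(self.signals)
        if self.signals.ndim != 3 or self.signals.shape[1:] != (
                N_CHANNELS, SAMPLES_PER_EPOCH):
            raise ValueError(
                f"signals must be (n, {N_CHANNELS}, {SAMPLES_PER_EPOCH}), "
                f"got {self.signals.shape}")
        if not (len(self.labels) == len(self.subject_ids)
                == len(self.recording_ids) == n):
            raise ValueError("per-epoch field lengths disagree")
        if n and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError("labels must lie in 0..4")
        if any(not sid for sid in self.subject_ids):
            raise ValueError("subject_id must be non-empty for every epoch")

    def __len__(self) -> int:
        return len(self.signals)

    def select(self, index) -> "SleepEpochSet":
        return SleepEpochSet(self.signals[index], self.labels[index],
                             self.subject_ids[index],
                             self.recording_ids[index])

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLASSES)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s)
        return list(seen)

    @staticmethod
    def concatenate(parts: list["SleepEpochSet"]) -> "SleepEpochSet":
        return SleepEpochSet(
            np.concatenate([p.signals for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.recording_ids for p in parts]))

    # -- cache -------------------------------------------------------------
    def save(self, directory):
        """Cache as one array file plus one table of per-epoch metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "signals.npy",
                self.signals.astype(np.float32))
        pd.DataFrame({
            "label": self.labels,
            "subject_id": self.subject_ids,
            "recording_id": self.recording_ids,
        }).to_csv(directory / "epochs.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SleepEpochSet":
        directory = Path(directory)
        signals = np.load(directory / "signals.npy")
        table = pd.read_csv(directory / "epochs.csv")
        return cls(signals, table["label"].to_numpy(),
                   table["subject_id"].astype(str).to_numpy(),
                   table["recording_id"].astype(str).to_numpy())


def map_labels(track: AnnotationTrack) -> np.ndarray:
    """Expand scored intervals into one label per 30 s slot.

    Returns class indices (0..4) with ``EXCLUDED`` (-1) for movement /
    unscored slots.  An unrecognized label text raises, listing the string.
    """
    if not track.events:
        return np.empty(0, dtype=np.int64)
    end = max(onset + duration for onset, duration, _ in track.events)
    n_slots = int(end // EPOCH_SEC)
    slots = np.full(n_slots, EXCLUDED, dtype=np.int64)
    for onset, duration, label in track.events:
        if label not in LABEL_MAP:
            raise UnknownStageLabelError(
                f"unknown sleep-stage annotation {label!r}; known: "
                f"{sorted(LABEL_MAP)}")
        first = int(round(onset / EPOCH_SEC))
        count = int(duration // EPOCH_SEC)
        slots[first:first + count] = LABEL_MAP[label]
    return slots


def epoch_and_trim(recording: TimeSeriesRecording, slot_labels: np.ndarray,
                   wake_margin_min: float = 30.0) -> SleepEpochSet:
    """Cut the recording into labeled (4, 3000) epochs with wake trimming.

    Excluded slots are dropped.  Wake epochs more than ``wake_margin_min``
    minutes before the first non-wake epoch, or after the last, are dropped;
    a recording containing no sleep at all cannot anchor the trimming and
    raises.
    """
    signal = recording.to_array()
    if signal.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got "
                         f"{signal.shape[0]}")
    slot_labels = np.asarray(slot_labels)
    n_slots = min(len(slot_labels), signal.shape[1] // SAMPLES_PER_EPOCH)
    if n_slots < len(slot_labels):
        logger.warning("recording %s shorter than its annotations: keeping "
                       "%d of %d slots", recording.recording_id, n_slots,
                       len(slot_labels))
    labels = slot_labels[:n_slots]

    keep = labels != EXCLUDED
    non_wake = np.flatnonzero((labels > 0) & keep)
    if non_wake.size == 0:
        raise ValueError(
            f"recording {recording.recording_id} has no sleep epochs; "
            "cannot anchor wake trimming")
    margin_slots = int(round(wake_margin_min * 60.0 / EPOCH_SEC))
    lo = max(0, non_wake[0] - margin_slots)
    hi = min(n_slots, non_wake[-1] + 1 + margin_slots)
    keep &= (np.arange(n_slots) >= lo) & (np.arange(n_slots) < hi)

    idx = np.flatnonzero(keep)
    epochs = np.stack([
        signal[:, i * SAMPLES_PER_EPOCH:(i + 1) * SAMPLES_PER_EPOCH]
        for i in idx]) if idx.size else np.empty(
            (0, N_CHANNELS, SAMPLES_PER_EPOCH))
    n = len(idx)
    return SleepEpochSet(
        epochs, labels[idx],
        np.array([recording.subject_id] * n, dtype=object),
        np.array([recording.recording_id] * n, dtype=object))


def normalize(epochs: SleepEpochSet, eps: float = 1e-8) -> SleepEpochSet:
    """Per-recording, per-channel z-score over all retained samples.

    A constant channel maps to all-zeros via the ``eps`` guard.  The
    operation is idempotent up to floating-point error.
    """
    signals = epochs.signals.astype(np.float64).copy()
    for rec in np.unique(epochs.recording_ids.astype(str)):
        mask = epochs.recording_ids.astype(str) == rec
        block = signals[mask]  # (n, 4, 3000)
        mu = block.mean(axis=(0, 2), keepdims=True)
        sd = block.std(axis=(0, 2), keepdims=True)
        signals[mask] = (block - mu) / (sd + eps)
    return SleepEpochSet(signals, epochs.labels, epochs.subject_ids,
                         epochs.recording_ids)


def prepare_recording(recording: TimeSeriesRecording,
                      track: AnnotationTrack,
                      wake_margin_min: float = 30.0,
                      do_normalize: bool = True) -> SleepEpochSet:
    """Full path: label mapping, epoching, trimming, normalization."""
    epochs = epoch_and_trim(recording, map_labels(track), wake_margin_min)
    return normalize(epochs) if do_normalize else epochs
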