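"""Synthetic polysomnography with stage-discriminable structure.

The generator emulates the band-power and transient cues that distinguish
sleep stages in real PSG — alpha-dominant relaxed wake, theta plus slow
rolling eye movements in N1, spindles and K-complexes in N2, high-amplitude
delta in N3, rapid EOG deflections with muscle atonia in REM — on top of a
1/f^beta background, with a first-order Markov hypnogram whose stationary
distribution mirrors the strong class imbalance of overnight recordings
(N1 rare, N2 dominant).  It exists so the whole pipeline and network can be
trained and tested end to end without downloading a benchmark; it makes no
claim to physiological realism beyond these statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .edf_io import (EPOCH_SEC, TARGET_RATE, AnnotationTrack, Channel,
                     TimeSeriesRecording, write_edf)
from .preprocess import (N_CLASSES, SAMPLES_PER_EPOCH, STAGE_NAMES,
                         SleepEpochSet, normalize)

#: Sleep-EDF-20 stage proportions (W, N1, N2, N3, REM); the default
#: hypnogram's stationary distribution.
DEFAULT_STAGE_PROPORTIONS = np.array([0.196, 0.066, 0.421, 0.135, 0.182])

_STAGE_TO_ANNOTATION = {0: "Sleep stage W", 1: "Sleep stage 1",
                        2: "Sleep stage 2", 3: "Sleep stage 3",
                        4: "Sleep stage R"}


@dataclass
class StageParams:
    """Spectral recipe for one stage.

    ``eeg_bands`` and ``eog_bands`` are (center Hz, half-bandwidth Hz,
    amplitude µV) triples; ``emg_tone`` is the RMS scale of the chin EMG.
    """

    eeg_bands: list[tuple[float, float, float]] = field(default_factory=list)
    eog_bands: list[tuple[float, float, float]] = field(default_factory=list)
    emg_tone: float = 10.0
    spindle_rate: float = 0.0       # 12-14 Hz bursts per epoch (N2)
    kcomplex_rate: float = 0.0      # biphasic pulses per epoch (N2)
    rem_deflection_rate: float = 0.0  # rapid EOG deflections per epoch


@dataclass
class StageSignalModel:
    """Per-stage signal recipes plus the shared 1/f background."""

    stages: dict[int, StageParams] = field(default_factory=dict)
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_scale: float = 6.0     # background RMS, µV
    second_eeg_gain: float = 0.7  # Pz-Oz relative to Fpz-Cz

    def __post_init__(self):
        if not self.stages:
            self.stages = _default_stage_params()
        if set(self.stages) != set(range(N_CLASSES)):
            raise ValueError("stage set must be {0..4}")
        tones = [self.stages[k].emg_tone for k in range(N_CLASSES)]
        for params in self.stages.values():
            for bands in (params.eeg_bands, params.eog_bands):
                if any(amp < 0 for _, _, amp in bands):
                    raise ValueError("band amplitudes must be >= 0")
        w, n1, n2, n3, rem = tones
        if not (w > n1 >= n2 >= n3 > rem):
            raise ValueError("EMG tone must satisfy W > N1 >= N2 >= N3 > REM")

    @classmethod
    def from_yaml(cls, path) -> "StageSignalModel":
        raw = yaml.safe_load(Path(path).read_text())
        stages = {int(k): StageParams(
            eeg_bands=[tuple(b) for b in v.get("eeg_bands", [])],
            eog_bands=[tuple(b) for b in v.get("eog_bands", [])],
            emg_tone=v.get("emg_tone", 10.0),
            spindle_rate=v.get("spindle_rate", 0.0),
            kcomplex_rate=v.get("kcomplex_rate", 0.0),
            rem_deflection_rate=v.get("rem_deflection_rate", 0.0),
        ) for k, v in raw.get("stages", {}).items()}
        return cls(stages=stages,
                   noise_exponent=raw.get("noise_exponent", 1.0),
                   noise_scale=raw.get("noise_scale", 6.0),
                   second_eeg_gain=raw.get("second_eeg_gain", 0.7))

    @classmethod
    def eeg_ambiguous_rem(cls) -> "StageSignalModel":
        """Variant whose REM/W contrast lives only in EOG and EMG.

        REM borrows the wake EEG recipe, so EEG-only models must confuse the
        two stages while the multimodal model can separate them — the
        architecture-sensitivity probe used in the training tests.
        """
        model = cls()
        wake = model.stages[0]
        rem = model.stages[4]
        rem.eeg_bands = [tuple(b) for b in wake.eeg_bands]
        return model


def _default_stage_params() -> dict[int, StageParams]:
    return {
        0: StageParams(  # relaxed wake: alpha rhythm, high muscle tone
            eeg_bands=[(10.0, 1.5, 30.0), (20.0, 4.0, 5.0)],
            eog_bands=[(0.3, 0.15, 15.0)],
            emg_tone=30.0),
        1: StageParams(  # N1: theta, slow rolling eye movements
            eeg_bands=[(5.5, 1.5, 25.0), (10.0, 1.5, 6.0)],
            eog_bands=[(0.4, 0.15, 45.0)],
            emg_tone=15.0),
        2: StageParams(  # N2: theta background + spindles + K-complexes
            eeg_bands=[(5.5, 1.5, 22.0)],
            eog_bands=[(0.3, 0.1, 8.0)],
            emg_tone=12.0, spindle_rate=3.0, kcomplex_rate=1.5),
        3: StageParams(  # N3: dominant slow waves
            eeg_bands=[(1.2, 0.6, 110.0), (5.5, 1.5, 10.0)],
            eog_bands=[(0.3, 0.1, 8.0)],
            emg_tone=10.0),
        4: StageParams(  # REM: low-amplitude mixed EEG, eye movements, atonia
            eeg_bands=[(5.5, 1.5, 18.0), (2.0, 0.8, 8.0)],
            eog_bands=[(0.4, 0.2, 10.0)],
            emg_tone=3.0, rem_deflection_rate=4.0),
    }


@dataclass
class HypnogramModel:
    """First-order Markov model over the five stages."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    n_epochs: int = 960  # one 8 h night

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix,
                                            dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution,
                                               dtype=float)
        P, pi0 = self.transition_matrix, self.initial_distribution
        if P.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("transition matrix must be 5x5")
        if (P < 0).any() or (pi0 < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition-matrix rows must sum to 1")
        if not np.isclose(pi0.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def default(cls, n_epochs: int = 960,
                persistence: float = 0.88) -> "HypnogramModel":
        """Sticky chain whose stationary law matches the benchmark imbalance.

        ``P = d I + (1-d) 1 pi^T`` has stationary distribution ``pi`` exactly
        and strong self-transitions (diagonal 0.89-0.93 at the default
        persistence), mimicking the minutes-long runs of real hypnograms.
        """
        pi = DEFAULT_STAGE_PROPORTIONS / DEFAULT_STAGE_PROPORTIONS.sum()
        P = persistence * np.eye(N_CLASSES) + (1 - persistence) * pi[None, :]
        start = np.zeros(N_CLASSES)
        start[0] = 1.0  # nights begin awake
        return cls(P, start, n_epochs)

    @classmethod
    def from_yaml(cls, path) -> "HypnogramModel":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(raw["transition_matrix"], dtype=float),
                   np.asarray(raw["initial_distribution"], dtype=float),
                   int(raw.get("n_epochs", 960)))

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of the transition matrix."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


def simulate_hypnogram(model: HypnogramModel,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a stage sequence of length ``model.n_epochs``."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cum = np.cumsum(model.transition_matrix, axis=1)
    stages = np.empty(model.n_epochs, dtype=np.int64)
    state = int(np.searchsorted(np.cumsum(model.initial_distribution),
                                rng.random()))
    for i in range(model.n_epochs):
        stages[i] = state
        state = int(np.searchsorted(cum[state], rng.random()))
    return stages


# -- waveform building blocks ---------------------------------------------

_T = np.arange(SAMPLES_PER_EPOCH) / TARGET_RATE


def _pink_noise(rng: np.random.Generator, beta: float,
                scale: float) -> np.ndarray:
    """1/f^beta Gaussian background, normalized to RMS ``scale``."""
    n = SAMPLES_PER_EPOCH
    freqs = np.fft.rfftfreq(n, d=1.0 / TARGET_RATE)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x * (scale / rms) if rms > 0 else x


def _band_oscillation(rng: np.random.Generator, center: float,
                      half_bw: float, amplitude: float) -> np.ndarray:
    """Random-phase sinusoid at a frequency drawn from the band, with a
    slow random amplitude envelope (burst-like waxing and waning)."""
    f = rng.uniform(center - half_bw, center + half_bw)
    phase = rng.uniform(0, 2 * np.pi)
    env = 1.0 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.05, 0.3) * _T
                             + rng.uniform(0, 2 * np.pi))
    return amplitude * env * np.sin(2 * np.pi * f * _T + phase)


def _burst(rng: np.random.Generator, freq: float, amplitude: float,
           duration_s: float) -> np.ndarray:
    """A Hann-windowed oscillatory burst at a random onset."""
    out = np.zeros(SAMPLES_PER_EPOCH)
    width = int(duration_s * TARGET_RATE)
    start = rng.integers(0, SAMPLES_PER_EPOCH - width)
    t = np.arange(width) / TARGET_RATE
    win = np.hanning(width)
    out[start:start + width] = amplitude * win * np.sin(
        2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return out


def _biphasic_pulse(rng: np.random.Generator, amplitude: float,
                    duration_s: float = 0.7) -> np.ndarray:
    """K-complex-like sharp negative-then-positive deflection."""
    out = np.zeros(SAMPLES_PER_EPOCH)
    width = int(duration_s * TARGET_RATE)
    start = rng.integers(0, SAMPLES_PER_EPOCH - width)
    t = np.linspace(-1, 1, width)
    out[start:start + width] = -amplitude * t * np.exp(-4 * t ** 2) * 2
    return out


def _eog_deflection(rng: np.random.Generator, amplitude: float,
                    duration_s: float = 0.5) -> np.ndarray:
    """Rapid-eye-movement step: a one-sided smooth deflection."""
    out = np.zeros(SAMPLES_PER_EPOCH)
    width = int(duration_s * TARGET_RATE)
    start = rng.integers(0, SAMPLES_PER_EPOCH - width)
    sign = rng.choice([-1.0, 1.0])
    out[start:start + width] = sign * amplitude * np.hanning(width)
    return out


def synthesize_epoch(stage: int, model: StageSignalModel | None = None,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """One (4, 3000) epoch of the given stage: EEG x2, EOG, EMG in µV."""
    if not 0 <= stage < N_CLASSES:
        raise ValueError(f"stage must be in 0..4, got {stage}")
    model = model or StageSignalModel()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = model.stages[int(stage)]

    def eeg_channel(gain: float) -> np.ndarray:
        x = _pink_noise(rng, model.noise_exponent, model.noise_scale)
        for center, bw, amp in params.eeg_bands:
            x += gain * _band_oscillation(rng, center, bw, amp)
        for _ in range(rng.poisson(params.spindle_rate)):
            x += gain * _burst(rng, rng.uniform(12.0, 14.0), 30.0, 1.0)
        for _ in range(rng.poisson(params.kcomplex_rate)):
            x += gain * _biphasic_pulse(rng, 80.0)
        return x

    eeg1 = eeg_channel(1.0)
    eeg2 = eeg_channel(model.second_eeg_gain)

    eog = _pink_noise(rng, model.noise_exponent, model.noise_scale)
    for center, bw, amp in params.eog_bands:
        eog += _band_oscillation(rng, center, bw, amp)
    for _ in range(rng.poisson(params.rem_deflection_rate)):
        eog += _eog_deflection(rng, 120.0)

    emg = params.emg_tone * rng.normal(size=SAMPLES_PER_EPOCH)
    emg += _pink_noise(rng, model.noise_exponent, 1.0)

    return np.stack([eeg1, eeg2, eog, emg])


def make_dataset(n_subjects: int = 10, epochs_per_subject: int = 200,
                 hyp_model: HypnogramModel | None = None,
                 sig_model: StageSignalModel | None = None,
                 seed: int = 0, do_normalize: bool = True,
                 export_dir=None) -> SleepEpochSet:
    """Simulate a cohort of synthetic subjects.

    Each subject gets an independent child seed derived from ``seed``, a
    Markov hypnogram, and stage-conditional signals.  With ``export_dir``
    every subject is also written out as a PSG EDF plus an EDF+ hypnogram
    file, exercising the full file-ingestion path.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    hyp = hyp_model or HypnogramModel.default()
    sig = sig_model or StageSignalModel()
    hyp = HypnogramModel(hyp.transition_matrix, hyp.initial_distribution,
                         epochs_per_subject)
    parts = []
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject = f"S{s:03d}"
        stages = simulate_hypnogram(hyp, rng)
        signals = np.stack([synthesize_epoch(st, sig, rng) for st in stages])
        part = SleepEpochSet(
            signals, stages,
            np.array([subject] * len(stages), dtype=object),
            np.array([f"{subject}R0"] * len(stages), dtype=object))
        if export_dir is not None:
            export_subject_edf(part, Path(export_dir), subject)
        parts.append(part)
    dataset = SleepEpochSet.concatenate(parts)
    return normalize(dataset) if do_normalize else dataset


def export_subject_edf(epochs: SleepEpochSet, directory: Path,
                       subject: str) -> tuple[Path, Path]:
    """Write one subject's epochs as PSG EDF + hypnogram EDF+ files."""
    directory.mkdir(parents=True, exist_ok=True)
    flat = np.concatenate(list(epochs.signals), axis=1)  # (4, n*3000)
    rec = TimeSeriesRecording(
        recording_id=f"{subject}R0", subject_id=subject,
        channels=[Channel("EEG Fpz-Cz", flat[0], TARGET_RATE),
                  Channel("EEG Pz-Oz", flat[1], TARGET_RATE),
                  Channel("EOG horizontal", flat[2], TARGET_RATE),
                  Channel("EMG submental", flat[3], TARGET_RATE)])
    events = []
    start = 0
    labels = epochs.labels
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            events.append((start * EPOCH_SEC, (i - start) * EPOCH_SEC,
                           _STAGE_TO_ANNOTATION[int(labels[start])]))
            start = i
    psg = write_edf(directory / f"{subject}-PSG.edf", rec)
    hyp = write_edf(directory / f"{subject}-Hypnogram.edf", None,
                    AnnotationTrack(events))
    return psg, hyp


def band_power_features(signals: np.ndarray) -> np.ndarray:
    """Simple per-epoch spectral features (used by sanity checks).

    Per EEG channel: log power in delta, theta, alpha, sigma, beta bands;
    for EOG: log low-frequency (<1 Hz) power; for EMG: log RMS.
    """
    from scipy.signal import welch

    bands = [(0.5, 2.0), (4.0, 7.0), (8.0, 12.0), (12.0, 14.0),
             (15.0, 30.0)]
    feats = []
    for ch in range(2):
        f, p = welch(signals[:, ch, :], fs=TARGET_RATE, nperseg=512, axis=-1)
        for lo, hi in bands:
            sel = (f >= lo) & (f <= hi)
            feats.append(np.log(p[:, sel].sum(axis=1) + 1e-12))
    f, p = welch(signals[:, 2, :], fs=TARGET_RATE, nperseg=512, axis=-1)
    feats.append(np.log(p[:, f <= 1.0].sum(axis=1) + 1e-12))
    feats.append(np.log(p[:, (f >= 1.0) & (f <= 5.0)].sum(axis=1) + 1e-12))
    feats.append(np.log(np.sqrt((signals[:, 3, :] ** 2).mean(axis=1))
                        + 1e-12))
    return np.stack(feats, axis=1)
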