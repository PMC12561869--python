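"""Reading and writing polysomnography in EDF/EDF+ format.

Reading goes through :mod:`mne` (``mne.io.read_raw_edf`` for signals,
``mne.read_annotations`` for hypnogram files in the EDF+ annotation dialect
used by the Sleep-EDF Database Expanded, where events carry labels such as
"Sleep stage W" / "Sleep stage 1" / "Movement time").

Writing is a small 16-bit EDF/EDF+ serializer used to produce synthetic
fixtures, so the whole ingestion path can be exercised without downloading
the benchmark.  Signals are quantized to the 16-bit digital range of their
physical span, which bounds the round-trip error by (physical range) / 2^15.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Sleep-EDF channel-label patterns for the four-channel model input,
#: in the fixed channel order the network expects.
DEFAULT_CHANNEL_SPEC = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal",
                        "EMG submental")

TARGET_RATE = 100.0  # Hz; the common rate all channels are brought to

EPOCH_SEC = 30.0


@dataclass
class Channel:
    label: str
    samples: np.ndarray  # µV
    sampling_rate: float  # Hz


@dataclass
class TimeSeriesRecording:
    """Multichannel signal for one night, resampled to a common rate."""

    recording_id: str
    subject_id: str
    channels: list[Channel]
    start_time: float = 0.0

    def __post_init__(self):
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels: {labels}")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].samples) if self.channels else 0

    def to_array(self) -> np.ndarray:
        """(n_channels, n_samples); requires equal lengths."""
        lengths = {len(c.samples) for c in self.channels}
        if len(lengths) > 1:
            raise ValueError(f"unequal channel lengths: {sorted(lengths)}")
        return np.stack([c.samples for c in self.channels])


@dataclass
class AnnotationTrack:
    """Scored intervals: (onset s, duration s, label)."""

    events: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        onsets = [e[0] for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            self.events = sorted(self.events, key=lambda e: e[0])


class MissingChannelError(KeyError):
    pass


class EdfFormatError(ValueError):
    pass


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Bring one channel to the common rate.

    Upsampling uses linear interpolation (the Sleep-EDF chin EMG is stored at
    1 Hz and only carries a slow tone envelope); downsampling goes through a
    polyphase anti-aliased resampler.
    """
    if rate_in == rate_out:
        return x
    n_out = int(round(len(x) * rate_out / rate_in))
    if rate_out > rate_in:
        t_in = np.arange(len(x)) / rate_in
        t_out = np.arange(n_out) / rate_out
        return np.interp(t_out, t_in, x)
    from scipy.signal import resample_poly
    from fractions import Fraction
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    y = resample_poly(x, frac.numerator, frac.denominator)
    return y[:n_out]


def read_psg(path, channel_spec=DEFAULT_CHANNEL_SPEC,
             target_rate: float = TARGET_RATE,
             recording_id: str | None = None,
             subject_id: str | None = None) -> TimeSeriesRecording:
    """Read the requested channels from an EDF/EDF+ PSG file.

    ``channel_spec`` entries are case-insensitive substring patterns matched
    against the channel labels in the file ("emg" matches "EMG submental").
    Channels come back calibrated to µV and resampled to ``target_rate``.
    Auxiliary channels (event markers, rectal temperature, ...) are ignored
    unless explicitly requested.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True,
                                      verbose="error")
    except Exception as exc:  # surface mne's parse failure with the path
        raise EdfFormatError(f"cannot parse EDF file {path}: {exc}") from exc

    channels: list[Channel] = []
    for pattern in channel_spec:
        matches = [name for name in raw.ch_names
                   if pattern.lower() in name.lower()]
        if not matches:
            raise MissingChannelError(
                f"no channel matching {pattern!r} in {path.name}; "
                f"available: {raw.ch_names}")
        name = matches[0]
        data = raw.get_data(picks=[name])[0] * 1e6  # volts -> µV
        samples = _resample(data, raw.info["sfreq"], target_rate)
        channels.append(Channel(name, samples.astype(np.float64),
                                target_rate))

    rid = recording_id or path.stem
    return TimeSeriesRecording(recording_id=rid,
                               subject_id=subject_id or rid,
                               channels=channels)


def read_hypnogram(path) -> AnnotationTrack:
    """Read an EDF+ annotation file into an :class:`AnnotationTrack`.

    Zero-duration bookkeeping annotations are dropped.  Durations that are
    not multiples of 30 s are kept but logged, since the epoching step
    truncates to whole 30 s slots.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ann = mne.read_annotations(str(path))
    except Exception as exc:
        raise EdfFormatError(
            f"no EDF+ annotation signal in {path}: {exc}") from exc

    events = []
    for onset, duration, label in zip(ann.onset, ann.duration,
                                      ann.description):
        if duration <= 0:
            continue
        if duration % EPOCH_SEC != 0:
            logger.warning("event %r at %gs has duration %gs, not a "
                           "multiple of %gs", label, onset, duration,
                           EPOCH_SEC)
        events.append((float(onset), float(duration), str(label)))
    return AnnotationTrack(events=events)


# -- writer ----------------------------------------------------------------

def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EdfFormatError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _tal_record(record_index: int, annotations) -> bytes:
    """One annotation data record; all events go in record 0."""
    tal = f"+{record_index}\x14\x14".encode("ascii") + b"\x00"
    if record_index == 0:
        for onset, duration, label in annotations:
            tal += (f"+{onset:g}\x15{duration:g}\x14{label}\x14"
                    .encode("utf-8") + b"\x00")
    return tal


def write_edf(path, recording: TimeSeriesRecording | None,
              annotations: AnnotationTrack | None = None,
              physical_limits: tuple[float, float] | None = None) -> Path:
    """Write a 16-bit EDF (or EDF+ when annotations are given) file.

    With ``physical_limits=(pmin, pmax)`` every channel shares that declared
    calibration range and samples outside it raise; otherwise each channel is
    scaled to its own observed range.  One-second data records are used, so
    channel sampling rates must be integers.
    """
    path = Path(path)
    events = annotations.events if annotations is not None else []
    channels = recording.channels if recording is not None else []
    has_ann = annotations is not None

    digital = []
    for ch in channels:
        rate = ch.sampling_rate
        if rate != int(rate):
            raise EdfFormatError(
                f"channel {ch.label!r}: non-integer rate {rate}")
        x = np.asarray(ch.samples, dtype=np.float64)
        if physical_limits is not None:
            pmin, pmax = physical_limits
            if x.size and (x.min() < pmin or x.max() > pmax):
                raise EdfFormatError(
                    f"channel {ch.label!r}: amplitude outside declared "
                    f"physical range [{pmin}, {pmax}]")
        else:
            pmin = float(x.min()) if x.size else -1.0
            pmax = float(x.max()) if x.size else 1.0
            if pmax <= pmin:
                pmax = pmin + 1.0
        dmin, dmax = -32768, 32767
        gain = (pmax - pmin) / (dmax - dmin)
        dig = np.round((x - pmin) / gain + dmin).astype("<i2")
        digital.append((ch.label, dig, int(rate), pmin, pmax, dmin, dmax))

    if channels:
        n_records = int(np.ceil(max(len(c.samples) / c.sampling_rate
                                    for c in channels)))
    elif events:
        n_records = 1
    else:
        n_records = 1

    tals = [_tal_record(r, events) for r in range(n_records)]
    ann_n = 0
    if has_ann:
        ann_n = max(len(t) for t in tals)
        ann_n += ann_n % 2
    ns = len(digital) + (1 if has_ann else 0)

    hdr = io.BytesIO()
    hdr.write(_field("0", 8))
    hdr.write(_field("X X X X", 80))
    hdr.write(_field(f"Startdate 01-JAN-2000 {recording.recording_id if recording else 'X'} X X"[:80], 80))
    hdr.write(_field("01.01.00", 8))
    hdr.write(_field("00.00.00", 8))
    hdr.write(_field(256 * (ns + 1), 8))
    hdr.write(_field("EDF+C" if has_ann else "", 44))
    hdr.write(_field(n_records, 8))
    hdr.write(_field(1, 8))  # record duration, seconds
    hdr.write(_field(ns, 4))

    labels = [d[0] for d in digital] + (["EDF Annotations"] if has_ann else [])
    for lab in labels:
        hdr.write(_field(lab[:16], 16))
    for _ in labels:
        hdr.write(_field("", 80))  # transducer
    for d in digital:
        hdr.write(_field("uV", 8))
    if has_ann:
        hdr.write(_field("", 8))
    for d in digital:
        hdr.write(_field(f"{d[3]:.6g}"[:8], 8))
    if has_ann:
        hdr.write(_field(-1, 8))
    for d in digital:
        hdr.write(_field(f"{d[4]:.6g}"[:8], 8))
    if has_ann:
        hdr.write(_field(1, 8))
    for d in digital:
        hdr.write(_field(d[5], 8))
    if has_ann:
        hdr.write(_field(-32768, 8))
    for d in digital:
        hdr.write(_field(d[6], 8))
    if has_ann:
        hdr.write(_field(32767, 8))
    for _ in labels:
        hdr.write(_field("", 80))  # prefiltering
    for d in digital:
        hdr.write(_field(d[2], 8))  # samples per record
    if has_ann:
        hdr.write(_field(ann_n // 2, 8))
    for _ in labels:
        hdr.write(_field("", 32))

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for rec in range(n_records):
            for lab, dig, rate, *_ in digital:
                chunk = dig[rec * rate:(rec + 1) * rate]
                if len(chunk) < rate:
                    pad = np.full(rate - len(chunk), chunk[-1] if len(chunk)
                                  else 0, dtype="<i2")
                    chunk = np.concatenate([chunk, pad])
                fh.write(chunk.astype("<i2").tobytes())
            if has_ann:
                fh.write(tals[rec].ljust(ann_n, b"\x00"))
    return path
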