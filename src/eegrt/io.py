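"""Recording / event-table containers, file round-trips, and epoch extraction.

Recordings travel either as long-form CSV (a ``time_s`` column plus one column
per channel, values in microvolts — lossless) or as 16-bit EDF. EDF files are
read through :mod:`mne`; writing uses a minimal EDF+-compatible encoder defined
here, whose quantization error is bounded by the physical-range step of the
16-bit digitization.

Epoching follows a strict "no post-cue samples" convention: the cue onset is
mapped to a sample index by flooring, and the epoch is the half-open window of
``n_tsi`` samples ending immediately before that index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventTable",
    "EpochSet",
    "load_recording",
    "write_recording",
    "load_events",
    "write_events",
    "extract_tsi",
    "flag_artifact_epochs",
    "save_epochs",
    "load_epochs",
]


@dataclass
class Recording:
    """A continuous multichannel EEG time series in microvolts.

    ``data`` is (n_channels, n_samples); ``channel_labels`` gives the montage
    order and must match the number of rows.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventTable:
    """Per-trial cue-onset and response timestamps (seconds from record start).

    The reaction delay of trial *i* is ``response_s[i] - cue_onset_s[i]`` and
    must be strictly positive.
    """

    cue_onset_s: np.ndarray
    response_s: np.ndarray
    trial_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cue_onset_s = np.asarray(self.cue_onset_s, dtype=float)
        self.response_s = np.asarray(self.response_s, dtype=float)
        if self.cue_onset_s.shape != self.response_s.shape:
            raise ValueError("cue_onset_s and response_s length mismatch")
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.cue_onset_s))
        self.trial_ids = np.asarray(self.trial_ids)
        if np.any(np.diff(self.cue_onset_s) <= 0):
            raise ValueError("cue onsets must be strictly increasing")
        if np.any(self.delay_s <= 0):
            raise ValueError("every response must come after its cue")

    @property
    def delay_s(self) -> np.ndarray:
        return self.response_s - self.cue_onset_s

    @property
    def n_trials(self) -> int:
        return len(self.cue_onset_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial_ids,
                "cue_onset_s": self.cue_onset_s,
                "response_s": self.response_s,
            }
        )


@dataclass
class EpochSet:
    """Stacked pre-cue windows: (n_trials, n_channels, n_tsi) in microvolts."""

    epochs: np.ndarray
    fs: float
    channel_labels: list[str]
    trial_ids: np.ndarray
    dropped_trial_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    rejected_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("EpochSet.epochs must be 3-D (trials x channels x samples)")
        self.trial_ids = np.asarray(self.trial_ids)
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.epochs.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_tsi(self) -> int:
        return self.epochs.shape[2]


# ---------------------------------------------------------------------------
# Recording file round-trips
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, format: str = "csv") -> Path:
    """Write a recording as long-form CSV or 16-bit EDF."""
    path = Path(path)
    if format == "csv":
        t = rec.start_time_s + np.arange(rec.n_samples) / rec.fs
        frame = pd.DataFrame({"time_s": t})
        for i, label in enumerate(rec.channel_labels):
            frame[label] = rec.data[i]
        frame.to_csv(path, index=False)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def load_recording(
    path: str | Path,
    format: str = "csv",
    required_channels: Sequence[str] | None = None,
) -> Recording:
    """Load a recording, converting to microvolts.

    For CSV the sampling rate is inferred from the ``time_s`` column, which
    must be regular to a relative jitter of 1e-6. ``required_channels`` (a
    montage list) raises a descriptive error if any channel is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        frame = pd.read_csv(path)
        if frame.empty or "time_s" not in frame.columns or frame.shape[1] < 2:
            raise ValueError(f"{path} is not a long-form recording CSV")
        t = frame["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path} holds fewer than two samples")
        dt = np.diff(t)
        dt_nominal = (t[-1] - t[0]) / (len(t) - 1)
        if dt_nominal <= 0 or np.any(np.abs(dt - dt_nominal) > 1e-6 * max(abs(t[-1]), 1.0)):
            raise ValueError(f"{path}: irregular sampling in time_s column")
        labels = [c for c in frame.columns if c != "time_s"]
        data = frame[labels].to_numpy(dtype=float).T
        rec = Recording(data=data, fs=1.0 / dt_nominal, channel_labels=labels,
                        start_time_s=float(t[0]))
    elif format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        rec = Recording(
            data=raw.get_data() * 1e6,  # mne loads volts
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )
    else:
        raise ValueError(f"unknown recording format {format!r}")

    if required_channels is not None:
        missing = [c for c in required_channels if c not in rec.channel_labels]
        if missing:
            raise ValueError(f"{path}: missing required channels {missing}")
    return rec


def _ascii_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} chars")
    return text.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit samples, per-channel physical scaling.

    Record layout: 1-second records when the sample count divides evenly,
    otherwise a single record spanning the whole signal. The physical min/max
    strings written to the header are parsed back for the digital scaling so
    the file is self-consistent at full header precision.
    """
    n_ch, n_samp = rec.data.shape
    fs = rec.fs
    if abs(fs - round(fs)) < 1e-9 and n_samp % round(fs) == 0 and n_samp // round(fs) >= 1:
        record_dur = 1.0
        samples_per_record = int(round(fs))
        n_records = n_samp // samples_per_record
    else:
        record_dur = n_samp / fs
        samples_per_record = n_samp
        n_records = 1

    phys_min, phys_max = [], []
    for i in range(n_ch):
        lo, hi = float(rec.data[i].min()), float(rec.data[i].max())
        # symmetric range with a short decimal repr that survives the 8-char
        # header field exactly; rounded outward so every sample stays in range
        span = max(abs(lo), abs(hi), 1e-3) * 1.001
        span = float(f"{span:.4g}")
        while span < max(abs(lo), abs(hi)):
            span = float(f"{span * 1.01:.4g}")
        phys_min.append(-span)
        phys_max.append(span)

    dig_min, dig_max = -32768, 32767
    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field("synthetic", 80)
    header += _ascii_field("eegrt export", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 + 256 * n_ch, 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(f"{record_dur:.8g}"[:8], 8)
    header += _ascii_field(n_ch, 4)
    for label in rec.channel_labels:
        header += _ascii_field(label[:16], 16)
    for _ in range(n_ch):
        header += _ascii_field("", 80)  # transducer
    for _ in range(n_ch):
        header += _ascii_field("uV", 8)
    for lo in phys_min:
        header += _ascii_field(f"{lo:.8g}"[:8], 8)
    for hi in phys_max:
        header += _ascii_field(f"{hi:.8g}"[:8], 8)
    for _ in range(n_ch):
        header += _ascii_field(dig_min, 8)
    for _ in range(n_ch):
        header += _ascii_field(dig_max, 8)
    for _ in range(n_ch):
        header += _ascii_field("", 80)  # prefiltering
    for _ in range(n_ch):
        header += _ascii_field(samples_per_record, 8)
    for _ in range(n_ch):
        header += _ascii_field("", 32)

    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for i in range(n_ch):
        scale = (dig_max - dig_min) / (phys_max[i] - phys_min[i])
        d = np.round((rec.data[i] - phys_min[i]) * scale + dig_min)
        digital[i] = np.clip(d, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = slice(r * samples_per_record, (r + 1) * samples_per_record)
            for i in range(n_ch):
                fh.write(digital[i, sl].tobytes())


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    events.to_frame().to_csv(path, index=False, float_format="%.12g")
    return path


def load_events(path: str | Path) -> EventTable:
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"trial", "cue_onset_s", "response_s"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: event CSV needs columns {sorted(required)}")
    return EventTable(
        cue_onset_s=frame["cue_onset_s"].to_numpy(dtype=float),
        response_s=frame["response_s"].to_numpy(dtype=float),
        trial_ids=frame["trial"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Epoch extraction and artifact screening
# ---------------------------------------------------------------------------

def extract_tsi(rec: Recording, events: EventTable, tsi_len_samples: int = 64) -> EpochSet:
    """Cut the pre-cue window of every trial.

    The cue onset maps to sample index ``floor(cue_onset_s * fs)``; the epoch
    is the half-open window ``[idx - tsi_len, idx)``, so no sample at or after
    the physical cue time can leak in. Trials whose window would start before
    sample 0 (or whose cue falls beyond the recording) are dropped and listed
    in ``dropped_trial_ids``.
    """
    if tsi_len_samples < 2:
        raise ValueError("tsi_len_samples must be at least 2")
    kept, dropped, windows = [], [], []
    for tid, onset in zip(events.trial_ids, events.cue_onset_s):
        idx = math.floor((onset - rec.start_time_s) * rec.fs)
        start = idx - tsi_len_samples
        if start < 0 or idx > rec.n_samples:
            dropped.append(tid)
            continue
        kept.append(tid)
        windows.append(rec.data[:, start:idx])
    if not kept:
        raise ValueError("no trial has a complete pre-cue window inside the recording")
    return EpochSet(
        epochs=np.stack(windows, axis=0),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        trial_ids=np.asarray(kept),
        dropped_trial_ids=np.asarray(dropped),
    )


def flag_artifact_epochs(epochs: EpochSet, k: float = 5.0) -> np.ndarray:
    """Flag epochs whose amplitude dwarfs the surrounding data.

    An epoch is flagged when on any channel its peak-to-peak amplitude exceeds
    ``k`` times that channel's median peak-to-peak across epochs. This is a
    screen only — callers decide whether to drop flagged trials (the default
    pipeline keeps everything and just reports).
    """
    if epochs.n_trials < 3:
        raise ValueError("artifact screening needs at least 3 epochs")
    ptp = epochs.epochs.max(axis=2) - epochs.epochs.min(axis=2)  # (trials, channels)
    med = np.median(ptp, axis=0)
    if np.isinf(k):
        return np.zeros(epochs.n_trials, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(med > 0, ptp / med, np.where(ptp > 0, np.inf, 1.0))
    return (ratio > k).any(axis=1)


# ---------------------------------------------------------------------------
# Epoch export (array + JSON sidecar)
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    arr_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(arr_path, epochs.epochs)
    meta = {
        "fs": epochs.fs,
        "channel_labels": epochs.channel_labels,
        "trial_ids": np.asarray(epochs.trial_ids).tolist(),
        "dropped_trial_ids": np.asarray(epochs.dropped_trial_ids).tolist(),
        "n_tsi": epochs.n_tsi,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return arr_path, meta_path


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EpochSet(
        epochs=data,
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        trial_ids=np.asarray(meta["trial_ids"]),
        dropped_trial_ids=np.asarray(meta["dropped_trial_ids"]),
    )
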