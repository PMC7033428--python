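"""Synthetic flight-session generator: EEG, cue schedule, and reaction delays.

A simulated session emulates a two-hour simulator flight recorded with a
14-channel, 128 Hz headset. Visual cues arrive with normally distributed
inter-arrival times (mean 2.5 min, sd 1 min, truncated below so cues cannot
pile up back to back). Each channel is a sum of band-limited oscillations —
one amplitude-modulated sinusoid per frequency band, carrier at the band
centre — on top of 1/f (pink) broadband noise band-limited to the headset's
useful range. Within the pre-cue window of each trial the oscillation
amplitudes take per-trial log-normal draws; elsewhere they sit at a baseline.

The reaction delay of trial *i* is generated from the planted oscillations:

    delay_i = max(floor, baseline + sum_cb coupling[c, b] * logvar_icb + eps_i)

where ``logvar_icb`` is the log-variance of the planted (channel, band)
component inside trial *i*'s pre-cue window and ``eps_i`` is Gaussian noise.
Log-normal amplitudes make these log-variances Gaussian, matching the
distributional motivation for the log transform downstream. A nonzero
coupling plants a recoverable brain-to-behaviour link; zero coupling gives a
null session for calibration checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .io import EventTable, Recording, write_events, write_recording
from .spectral import DEFAULT_BANDS, BandSpec

__all__ = [
    "DEFAULT_MONTAGE",
    "SimConfig",
    "GroundTruth",
    "Session",
    "simulate_cue_schedule",
    "simulate_delays",
    "synthesize_eeg",
    "simulate_session",
    "write_session",
]

#: 14-channel Emotiv subset of the 10-10 montage, in device order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


@dataclass
class SimConfig:
    """Parameters of one simulated session.

    ``coupling`` maps ``(channel_label, band_name)`` to a linear coefficient
    in seconds per log-variance unit; an empty map yields delays that are
    pure baseline + noise (a null session).
    """

    session_length_s: float = 7200.0
    fs: float = 128.0
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    cue_interval_mean_s: float = 150.0
    cue_interval_sd_s: float = 60.0
    min_gap_s: float = 10.0
    schedule_margin_s: float = 5.0
    tsi_seconds: float = 0.5
    coupling: Mapping[tuple[str, str], float] = field(default_factory=dict)
    delay_baseline_s: float = 0.55
    delay_noise_sd_s: float = 0.05
    delay_floor_s: float = 0.25
    band_base_amp_uv: float = 10.0
    band_amp_sigma: float = 0.6
    noise_rms_uv: float = 4.0
    noise_f_low_hz: float = 0.16
    noise_f_high_hz: float = 43.0
    mains_hz: float | None = None
    mains_amp_uv: float = 2.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_tsi(self) -> int:
        return int(round(self.tsi_seconds * self.fs))

    def validate(self) -> None:
        if self.session_length_s <= 0 or self.fs <= 0:
            raise ValueError("session length and sampling rate must be positive")
        if not (self.cue_interval_mean_s > self.cue_interval_sd_s >= 0):
            raise ValueError("need cue_interval_mean_s > cue_interval_sd_s >= 0")
        if self.delay_floor_s <= 0:
            raise ValueError("delay_floor_s must be positive")
        if self.cue_interval_sd_s > 0:
            discard = norm.cdf(self.min_gap_s, self.cue_interval_mean_s,
                               self.cue_interval_sd_s)
            if discard > 0.5:
                raise ValueError(
                    "degenerate cue-interval parameters: truncation at "
                    f"{self.min_gap_s} s would discard {100 * discard:.0f}% of draws"
                )
        band_names = {b.name for b in self.bands}
        for ch, band in self.coupling:
            if ch not in self.channel_labels:
                raise ValueError(f"coupling references unknown channel {ch!r}")
            if band not in band_names:
                raise ValueError(f"coupling references unknown band {band!r}")
        for b in self.bands:
            if b.center >= self.fs / 2:
                raise ValueError(
                    f"band {b.name!r} carrier {b.center} Hz is at or above Nyquist"
                )


@dataclass
class GroundTruth:
    """The planted signal of a session, kept for recovery tests.

    ``amplitudes`` and ``planted_logvar`` have shape
    (n_trials, n_channels, n_bands); ``phases`` is (n_channels, n_bands).
    """

    cue_onsets_s: np.ndarray
    true_delays_s: np.ndarray
    amplitudes: np.ndarray
    planted_logvar: np.ndarray
    phases: np.ndarray
    channel_labels: tuple[str, ...]
    band_names: tuple[str, ...]

    def logvar_of(self, channel: str, band: str) -> np.ndarray:
        c = self.channel_labels.index(channel)
        b = self.band_names.index(band)
        return self.planted_logvar[:, c, b]


@dataclass
class Session:
    recording: Recording
    events: EventTable
    ground_truth: GroundTruth
    config: SimConfig


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(5)
    names = ("schedule", "amplitudes", "phases", "delay_noise", "noise")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_cue_schedule(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw cue-onset times for one session.

    Inter-arrival gaps are normal draws truncated below at ``min_gap_s`` by
    resampling; the schedule stops before ``session_length_s`` minus a margin
    of one pre-cue window plus ``schedule_margin_s`` (room for the response).
    """
    config.validate()
    if rng is None:
        rng = _streams(config)["schedule"]
    horizon = config.session_length_s - (config.tsi_seconds + config.schedule_margin_s)
    onsets: list[float] = []
    t = 0.0
    while True:
        if config.cue_interval_sd_s == 0:
            gap = config.cue_interval_mean_s
        else:
            gap = rng.normal(config.cue_interval_mean_s, config.cue_interval_sd_s)
            while gap < config.min_gap_s:
                gap = rng.normal(config.cue_interval_mean_s, config.cue_interval_sd_s)
        t += gap
        if t >= horizon:
            break
        onsets.append(t)
    return np.asarray(onsets)


def _tsi_start_indices(schedule: np.ndarray, config: SimConfig) -> np.ndarray:
    """First sample of each pre-cue window (floor convention, as in epoching)."""
    return np.floor(schedule * config.fs).astype(int) - config.n_tsi


def _planted_logvar(
    schedule: np.ndarray,
    amplitudes: np.ndarray,
    phases: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Log-variance of each planted band component over its trial's window.

    Uses the same sample grid the synthesized recording puts inside the
    window, so the generative delay model and the signal agree exactly.
    """
    n_tsi = config.n_tsi
    starts = _tsi_start_indices(schedule, config)
    t = (starts[:, None] + np.arange(n_tsi)[None, :]) / config.fs  # (trials, n_tsi)
    n_tr, n_ch, n_bd = amplitudes.shape
    logvar = np.empty((n_tr, n_ch, n_bd))
    for b, band in enumerate(config.bands):
        phase_arg = 2 * np.pi * band.center * t  # (trials, n_tsi)
        for c in range(n_ch):
            seg = np.sin(phase_arg + phases[c, b])
            seg_var = seg.var(axis=1)  # population (1/N) variance
            logvar[:, c, b] = np.log(amplitudes[:, c, b] ** 2 * seg_var)
    return logvar


def simulate_delays(
    schedule: np.ndarray,
    planted_logvar: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate reaction delays from the planted band log-variances."""
    config.validate()
    if rng is None:
        rng = _streams(config)["delay_noise"]
    n = len(schedule)
    delays = np.full(n, config.delay_baseline_s)
    band_names = [b.name for b in config.bands]
    for (ch, band), coef in config.coupling.items():
        c = config.channel_labels.index(ch)
        b = band_names.index(band)
        delays = delays + coef * planted_logvar[:, c, b]
    if config.delay_noise_sd_s > 0:
        delays = delays + rng.normal(0.0, config.delay_noise_sd_s, size=n)
    return np.maximum(delays, config.delay_floor_s)


def _pink_noise(n: int, fs: float, rms: float, f_low: float, f_high: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited 1/f noise: white spectrum shaped by f^-1/2, scaled to rms."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    in_band = (freqs >= f_low) & (freqs <= f_high)
    shape[in_band] = 1.0 / np.sqrt(freqs[in_band])
    noise = np.fft.irfft(spectrum * shape, n=n)
    sd = noise.std()
    return noise * (rms / sd) if sd > 0 else noise


def synthesize_eeg(
    config: SimConfig, ground_truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Render the session's multichannel EEG in microvolts.

    Each channel sums one sinusoid per band (carrier at the band centre,
    amplitude = per-trial draw inside pre-cue windows, baseline elsewhere)
    with pink noise; an optional mains tone is off by default because the
    emulated headset notch-filters it.
    """
    config.validate()
    if rng is None:
        rng = _streams(config)["noise"]
    n = int(round(config.session_length_s * config.fs))
    t = np.arange(n) / config.fs
    starts = _tsi_start_indices(ground_truth.cue_onsets_s, config)
    n_tsi = config.n_tsi

    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        sig = np.zeros(n)
        for b, band in enumerate(config.bands):
            envelope = np.full(n, config.band_base_amp_uv)
            for i, s0 in enumerate(starts):
                if 0 <= s0 and s0 + n_tsi <= n:
                    envelope[s0:s0 + n_tsi] = ground_truth.amplitudes[i, c, b]
            carrier = np.sin(2 * np.pi * band.center * t + ground_truth.phases[c, b])
            sig += envelope * carrier
        sig += _pink_noise(n, config.fs, config.noise_rms_uv,
                           config.noise_f_low_hz, config.noise_f_high_hz, rng)
        if config.mains_hz is not None:
            sig += config.mains_amp_uv * np.sin(2 * np.pi * config.mains_hz * t)
        data[c] = sig
    return Recording(data=data, fs=config.fs,
                     channel_labels=list(config.channel_labels))


def simulate_session(config: SimConfig) -> Session:
    """Generate a full session: schedule, amplitudes, delays, EEG, events."""
    config.validate()
    streams = _streams(config)
    schedule = simulate_cue_schedule(config, streams["schedule"])
    if len(schedule) == 0:
        raise ValueError("session too short: no cue fits before the horizon")
    n_tr = len(schedule)
    n_ch, n_bd = config.n_channels, len(config.bands)
    amplitudes = config.band_base_amp_uv * np.exp(
        config.band_amp_sigma * streams["amplitudes"].standard_normal((n_tr, n_ch, n_bd))
    )
    phases = streams["phases"].uniform(0, 2 * np.pi, size=(n_ch, n_bd))
    planted_logvar = _planted_logvar(schedule, amplitudes, phases, config)
    delays = simulate_delays(schedule, planted_logvar, config, streams["delay_noise"])
    ground_truth = GroundTruth(
        cue_onsets_s=schedule,
        true_delays_s=delays,
        amplitudes=amplitudes,
        planted_logvar=planted_logvar,
        phases=phases,
        channel_labels=tuple(config.channel_labels),
        band_names=tuple(b.name for b in config.bands),
    )
    recording = synthesize_eeg(config, ground_truth, streams["noise"])
    events = EventTable(cue_onset_s=schedule, response_s=schedule + delays)
    return Session(recording=recording, events=events,
                   ground_truth=ground_truth, config=config)


def write_session(session: Session, out_dir: str | Path,
                  recording_format: str = "csv") -> dict[str, Path]:
    """Write recording, events, ground truth, and config under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if recording_format == "csv" else "edf"
    paths = {
        "recording": out_dir / f"recording.{ext}",
        "events": out_dir / "events.csv",
        "ground_truth": out_dir / "ground_truth.json",
        "config": out_dir / "sim_config.json",
    }
    write_recording(session.recording, paths["recording"], format=recording_format)
    write_events(session.events, paths["events"])
    gt = session.ground_truth
    paths["ground_truth"].write_text(json.dumps({
        "cue_onsets_s": gt.cue_onsets_s.tolist(),
        "true_delays_s": gt.true_delays_s.tolist(),
        "amplitudes": gt.amplitudes.tolist(),
        "planted_logvar": gt.planted_logvar.tolist(),
        "phases": gt.phases.tolist(),
        "channel_labels": list(gt.channel_labels),
        "band_names": list(gt.band_names),
    }))
    cfg = asdict(session.config)
    cfg["bands"] = [[b.name, b.f_low, b.f_high] for b in session.config.bands]
    cfg["coupling"] = [[ch, band, coef] for (ch, band), coef in
                       session.config.coupling.items()]
    paths["config"].write_text(json.dumps(cfg, indent=1))
    return paths
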