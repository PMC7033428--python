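"""Frequency-band decomposition of short EEG segments.

Each pre-cue segment is decomposed with a zero-padded FFT: the segment is
demeaned, extended with zeros to refine the frequency-bin spacing, transformed,
all Fourier amplitudes outside the requested band are set to zero, and the
band-limited time signal is recovered by the inverse transform. Only the
samples corresponding to the original (unpadded) segment are returned, so the
downstream bandpower features never describe the padding.

The default band bank covers the canonical EEG rhythms from delta up to low
gamma plus a broad 8-30 Hz sensorimotor range; with 64-sample segments padded
to 256 at 128 Hz the bin spacing is 0.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BandSpec",
    "BandSignalSet",
    "DEFAULT_BANDS",
    "fft_bandpass",
    "decompose_epochs",
]


@dataclass(frozen=True)
class BandSpec:
    """A half-open frequency band [f_low, f_high) in Hz.

    Half-open intervals keep shared band edges (4, 8, 12 ... Hz) from being
    counted in two neighbouring bands.
    """

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    def validate_for_fs(self, fs: float) -> None:
        if self.f_low >= fs / 2:
            raise ValueError(
                f"band {self.name!r} [{self.f_low}, {self.f_high}) lies entirely "
                f"at or above the Nyquist frequency {fs / 2} Hz"
            )
        if self.f_high > fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: Ten-band bank: the classical rhythms, two low-gamma bands (the 28-32 Hz gap
#: between HighBeta and Gamma1 is intentional) and a broad sensorimotor range.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("Delta", 1.0, 4.0),
    BandSpec("Theta", 4.0, 8.0),
    BandSpec("Alpha", 8.0, 12.0),
    BandSpec("LowBeta", 12.0, 16.0),
    BandSpec("MidBeta", 16.0, 20.0),
    BandSpec("MidHighBeta", 20.0, 24.0),
    BandSpec("HighBeta", 24.0, 28.0),
    BandSpec("Gamma1", 32.0, 36.0),
    BandSpec("Gamma2", 36.0, 40.0),
    BandSpec("Broad", 8.0, 30.0),
)


def _band_mask(pad_to: int, fs: float, band: BandSpec) -> np.ndarray:
    """Boolean keep-mask over the one-sided rfft bins. DC is never kept."""
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / fs)
    return (freqs >= band.f_low) & (freqs < band.f_high)


def fft_bandpass(
    x: np.ndarray, fs: float, band: BandSpec, pad_to: int = 256
) -> np.ndarray:
    """Band-limit a short real signal by zeroing out-of-band Fourier amplitudes.

    Parameters
    ----------
    x
        1-D real signal of length ``n``.
    fs
        Sampling rate in Hz.
    band
        Half-open frequency band to retain.
    pad_to
        Total FFT length after appending zeros (``pad_to >= n``). Padding
        refines the bin spacing to ``fs / pad_to`` without adding information.

    Returns
    -------
    The band-limited reconstruction, truncated back to the first ``n`` samples.

    Notes
    -----
    The segment mean is subtracted before padding and the DC bin is zeroed:
    the step between the signal's offset and the appended zeros would
    otherwise smear low-frequency energy into the spectrum, and no band in
    the bank extends below 1 Hz, so discarding DC is lossless for features.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fft_bandpass expects a 1-D signal")
    n = x.size
    if n < 2:
        raise ValueError(f"signal too short for band decomposition (n={n})")
    if pad_to < n:
        raise ValueError(f"pad_to={pad_to} is shorter than the signal (n={n})")
    band.validate_for_fs(fs)

    xp = np.zeros(pad_to)
    xp[:n] = x - x.mean()
    spectrum = np.fft.rfft(xp)
    spectrum[~_band_mask(pad_to, fs, band)] = 0.0
    return np.fft.irfft(spectrum, n=pad_to)[:n]


@dataclass
class BandSignalSet:
    """Band-limited reconstructions for every (trial, channel, band).

    ``data`` has shape (n_trials, n_channels, n_bands, n_tsi) in microvolts.
    """

    data: np.ndarray
    bands: tuple[BandSpec, ...]
    channel_labels: list[str]
    trial_ids: np.ndarray
    fs: float
    pad_to: int
    n_tsi: int = field(init=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BandSignalSet.data must be 4-D")
        self.n_tsi = self.data.shape[-1]

    @property
    def frequency_resolution(self) -> float:
        """Bin spacing of the padded transform, fs / pad_to (Hz)."""
        return self.fs / self.pad_to

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def decompose_epochs(
    epochs,
    bank: Sequence[BandSpec] = DEFAULT_BANDS,
    pad_to: int = 256,
) -> BandSignalSet:
    """Decompose every epoch channel into the bank's bands.

    Equivalent to calling :func:`fft_bandpass` independently for each
    (trial, channel, band) triple; the forward transform is shared across
    bands because zeroing bins commutes with the (linear) FFT.
    """
    if len(bank) == 0:
        raise ValueError("band bank is empty")
    data = np.asarray(epochs.epochs, dtype=float)
    n_trials, n_channels, n_tsi = data.shape
    if n_tsi < 2:
        raise ValueError("epochs are too short to decompose")
    if pad_to < n_tsi:
        raise ValueError(f"pad_to={pad_to} shorter than the epoch length {n_tsi}")
    fs = epochs.fs
    for band in bank:
        try:
            band.validate_for_fs(fs)
        except ValueError as exc:
            raise ValueError(f"invalid band in bank: {exc}") from exc

    padded = np.zeros((n_trials, n_channels, pad_to))
    padded[..., :n_tsi] = data - data.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(padded, axis=-1)

    out = np.empty((n_trials, n_channels, len(bank), n_tsi))
    for b, band in enumerate(bank):
        kept = np.where(_band_mask(pad_to, fs, band), spectrum, 0.0)
        out[:, :, b, :] = np.fft.irfft(kept, n=pad_to, axis=-1)[..., :n_tsi]

    return BandSignalSet(
        data=out,
        bands=tuple(bank),
        channel_labels=list(epochs.channel_labels),
        trial_ids=np.asarray(epochs.trial_ids),
        fs=fs,
        pad_to=pad_to,
    )
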