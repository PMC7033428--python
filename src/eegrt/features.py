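"""Log-variance bandpower features and leak-free standardization.

A band-limited signal has (near) zero mean, so its variance measures the
bandpower; taking the natural logarithm brings the heavy-tailed power
distribution close to normal. One feature per (channel, band) gives
channels x bands columns — 140 with the default 14-channel montage and
10-band bank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EventTable
from .spectral import BandSignalSet

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "logvar",
    "build_feature_matrix",
    "fit_standardizer",
    "apply_standardizer",
    "feature_matrix_to_csv",
    "feature_matrix_from_csv",
]


def logvar(x: np.ndarray) -> float:
    """Natural log of the sample variance (1/N convention) of a signal."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("logvar needs at least 2 samples")
    v = x.var()
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"non-positive variance {v}: dead channel or all-zero band")
    return float(np.log(v))


@dataclass
class FeatureMatrix:
    """Trials x (channel, band) log-variance features with delay targets.

    Columns are channel-major: all bands of the first montage channel, then
    the next channel, and so on. ``column_labels`` use the ``CHANNEL_Band``
    convention (e.g. ``AF3_Gamma1``).
    """

    values: np.ndarray
    column_labels: list[str]
    y: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2-D")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column label count does not match feature count")
        if self.values.shape[0] != len(self.y):
            raise ValueError("target vector length does not match trial count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_feature_matrix(bands: BandSignalSet, events: EventTable) -> FeatureMatrix:
    """Compute the logvar feature of every (trial, channel, band).

    Trials are aligned to the event table by trial id; a mismatch between the
    two trial sets is an error (listing the offending ids), because silently
    intersecting them would desynchronize features and targets.
    """
    band_ids = list(np.asarray(bands.trial_ids))
    ev_ids = list(np.asarray(events.trial_ids))
    unmatched = sorted(set(band_ids) ^ set(ev_ids))
    if unmatched:
        raise ValueError(f"trial ids differ between epochs and events: {unmatched}")

    order = {tid: i for i, tid in enumerate(ev_ids)}
    sort_idx = np.argsort([order[tid] for tid in band_ids], kind="stable")
    data = bands.data[sort_idx]  # (trials, channels, bands, n_tsi)
    trial_ids = np.asarray(bands.trial_ids)[sort_idx]

    variances = data.var(axis=-1)
    bad = np.argwhere(~(variances > 0) | ~np.isfinite(variances))
    if len(bad):
        i, c, b = bad[0]
        raise ValueError(
            f"zero-variance band signal at trial {trial_ids[i]}, channel "
            f"{bands.channel_labels[c]}, band {bands.bands[b].name}"
        )
    n_tr, n_ch, n_bd = variances.shape
    values = np.log(variances).reshape(n_tr, n_ch * n_bd)  # channel-major
    labels = [
        f"{ch}_{band.name}" for ch in bands.channel_labels for band in bands.bands
    ]
    y = np.asarray(events.delay_s)[[order[tid] for tid in trial_ids]]
    return FeatureMatrix(values=values, column_labels=labels, y=y,
                         trial_ids=trial_ids)


@dataclass
class Standardizer:
    """Per-column z-scoring statistics learned from a training subset."""

    mean_: np.ndarray
    sd_: np.ndarray
    column_labels: list[str]


def fit_standardizer(fm: FeatureMatrix, train_idx: np.ndarray) -> Standardizer:
    """Learn column means/sds from the training rows only (leak-free)."""
    train_idx = np.asarray(train_idx)
    if len(train_idx) < 2:
        raise ValueError("standardizer needs at least 2 training rows")
    train = fm.values[train_idx]
    mean = train.mean(axis=0)
    sd = train.std(axis=0)  # 1/N, matching the variance convention
    zero = np.where(sd == 0)[0]
    if len(zero):
        raise ValueError(
            f"zero training variance in column(s) {[fm.column_labels[i] for i in zero]}"
        )
    return Standardizer(mean_=mean, sd_=sd, column_labels=list(fm.column_labels))


def apply_standardizer(std: Standardizer, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply learned statistics unchanged to any rows (train or test)."""
    if std.column_labels != fm.column_labels:
        raise ValueError("standardizer was fit on different columns")
    return replace(fm, values=(fm.values - std.mean_) / std.sd_)


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(fm.values, columns=fm.column_labels)
    frame.insert(0, "trial", fm.trial_ids)
    frame["delay_s"] = fm.y
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def feature_matrix_from_csv(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path)
    labels = [c for c in frame.columns if c not in ("trial", "delay_s")]
    return FeatureMatrix(
        values=frame[labels].to_numpy(dtype=float),
        column_labels=labels,
        y=frame["delay_s"].to_numpy(dtype=float),
        trial_ids=frame["trial"].to_numpy(),
    )
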