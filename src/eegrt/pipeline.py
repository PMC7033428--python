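"""End-to-end orchestration: load -> epoch -> decompose -> features -> evaluate -> stats.

A run is described by a :class:`RunConfig` (constructible from YAML), executes
each stage in order, writes every stage product under the output directory,
and records a provenance manifest (config hash, derived segment/padding
lengths, seeds, package and library versions) so a rerun with the same
manifest reproduces the same numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import build_feature_matrix, feature_matrix_to_csv
from .io import extract_tsi, flag_artifact_epochs, load_events, load_recording
from .prediction import (
    ModelSpec,
    SplitScheme,
    default_model_specs,
    evaluate_subject,
    shuffled_baseline,
    summarize_selected_features,
)
from .spectral import DEFAULT_BANDS, BandSpec, decompose_epochs
from .stats import anova_oneway, pairwise_ttests, summarize_delays

__all__ = ["RunConfig", "build_manifest", "run_pipeline"]

log = logging.getLogger("eegrt")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    recording_path: str
    events_path: str
    recording_format: str = "csv"
    fs: float = 128.0
    tsi_seconds: float = 0.5
    pad_to: int = 256
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    montage: tuple[str, ...] | None = None
    artifact_k: float = 5.0
    drop_flagged: bool = False
    scheme: SplitScheme = field(default_factory=SplitScheme)
    model_specs: list[ModelSpec] | None = None
    include_shuffled_baseline: bool = True
    seed: int = 0

    @property
    def n_tsi(self) -> int:
        n = self.tsi_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"tsi_seconds * fs = {n} is not an integer sample count"
            )
        return int(round(n))

    def validate(self) -> None:
        if self.pad_to < self.n_tsi:
            raise ValueError(f"pad_to={self.pad_to} < segment length {self.n_tsi}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "bands" in raw:
            raw["bands"] = tuple(
                BandSpec(b["name"], float(b["low"]), float(b["high"]))
                for b in raw["bands"]
            )
        if "scheme" in raw:
            raw["scheme"] = SplitScheme(**raw["scheme"])
        if "model_specs" in raw:
            raw["model_specs"] = [
                ModelSpec(
                    m["algorithm"],
                    m.get("hyperparameter_grid", {}),
                    m.get("feature_selection_k_grid"),
                )
                for m in raw["model_specs"]
            ]
        if "montage" in raw and raw["montage"] is not None:
            raw["montage"] = tuple(raw["montage"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["bands"] = [[b.name, b.f_low, b.f_high] for b in self.bands]
        d["scheme"] = asdict(self.scheme)
        if self.model_specs is not None:
            d["model_specs"] = [asdict(m) for m in self.model_specs]
        return d


def build_manifest(config: RunConfig) -> dict:
    """Provenance record: config hash, derived lengths, seeds, versions."""
    config.validate()
    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    import scipy
    import sklearn

    return {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_tsi": config.n_tsi,
        "pad_zeros": config.pad_to - config.n_tsi,
        "fft_length": config.pad_to,
        "frequency_resolution_hz": config.fs / config.pad_to,
        "n_bands": len(config.bands),
        "seed": config.seed,
        "split_seeds": [config.scheme.base_seed + r
                        for r in range(config.scheme.n_repetitions)],
        "versions": {
            "eegrt": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all products under ``out_dir``.

    Returns a dict with the in-memory results and the paths written. Any
    stage failure aborts with the stage name attached.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    t0 = time.perf_counter()
    try:
        recording = load_recording(config.recording_path, config.recording_format,
                                   required_channels=config.montage)
        events = load_events(config.events_path)
        log.info("load: %d channels, %.0f s, %d events (%.2f s)",
                 len(recording.channel_labels), recording.duration_s,
                 events.n_trials, time.perf_counter() - t0)

        stage = "epoch"
        epochs = extract_tsi(recording, events, config.n_tsi)
        if len(epochs.dropped_trial_ids):
            log.info("epoch: dropped %d trial(s) too close to recording start",
                     len(epochs.dropped_trial_ids))

        stage = "artifact screen"
        flagged = flag_artifact_epochs(epochs, k=config.artifact_k)
        epochs.rejected_mask = flagged
        log.info("artifact screen: %d/%d epochs flagged (k=%.3g)%s",
                 int(flagged.sum()), epochs.n_trials, config.artifact_k,
                 "" if config.drop_flagged else " [report-only]")
        kept_events = events
        if config.drop_flagged and flagged.any():
            keep = ~flagged
            epochs.epochs = epochs.epochs[keep]
            epochs.trial_ids = epochs.trial_ids[keep]
            epochs.rejected_mask = epochs.rejected_mask[keep]
        if len(epochs.trial_ids) != events.n_trials:
            keep_ids = set(np.asarray(epochs.trial_ids).tolist())
            mask = np.array([tid in keep_ids for tid in events.trial_ids])
            from .io import EventTable

            kept_events = EventTable(events.cue_onset_s[mask],
                                     events.response_s[mask],
                                     events.trial_ids[mask])

        stage = "decompose"
        band_signals = decompose_epochs(epochs, config.bands, config.pad_to)

        stage = "features"
        fm = build_feature_matrix(band_signals, kept_events)
        features_path = feature_matrix_to_csv(fm, out_dir / "features.csv")

        stage = "evaluate"
        specs = config.model_specs or default_model_specs(fm.n_features)
        result = evaluate_subject(fm, specs, config.scheme)
        if config.include_shuffled_baseline:
            shuffled = shuffled_baseline(fm, config.scheme)
            result.per_rep.update(shuffled.per_rep)
        log.info("evaluate: %s", ", ".join(
            f"{a}={result.mae_s(a):.3f}s" for a in result.per_rep))

        stage = "stats"
        delay_summary = summarize_delays(kept_events)
        groups = {a: result.pooled_abs_errors(a) for a in result.per_rep}
        f_stat, p_anova = anova_oneway(list(groups.values()))
        ttests = pairwise_ttests(groups)
        selection = summarize_selected_features(result)

        stage = "report"
        results_json = {
            "evaluation": result.to_dict(),
            "delay_summary": delay_summary.to_row(),
            "anova": {"F": f_stat, "p": p_anova},
        }
        (out_dir / "results.json").write_text(json.dumps(results_json, indent=1))
        result.aggregates().to_csv(out_dir / "mae_table.csv", index=False,
                                   float_format="%.3f")
        ttests.to_csv(out_dir / "pairwise_ttests.csv", float_format="%.4g")
        selection.to_csv(out_dir / "selected_features.csv", index=False)
        pd.DataFrame([delay_summary.to_row()]).to_csv(
            out_dir / "delay_summary.csv", index=False, float_format="%.3f")
        manifest = build_manifest(config)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("run complete in %.1f s -> %s", time.perf_counter() - t0, out_dir)
    return {
        "features": fm,
        "evaluation": result,
        "delay_summary": delay_summary,
        "anova": (f_stat, p_anova),
        "pairwise_ttests": ttests,
        "selected_features": selection,
        "manifest": manifest,
        "out_dir": out_dir,
        "features_path": features_path,
    }
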