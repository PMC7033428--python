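#!/usr/bin/env python
"""Cut pre-cue segments, screen artifacts, and extract logvar bandpower features.

For each simulated session from 01: load the recording and events, cut the
64-sample pre-cue window of every trial, report amplitude-screened epochs
(report-only, matching the default analysis), decompose each window into the
10-band bank with the zero-padded FFT filter, and write the 140-column
log-variance feature matrix to scratch/.
"""

import argparse
from pathlib import Path

import numpy as np

from eegrt.features import build_feature_matrix, feature_matrix_to_csv
from eegrt.io import extract_tsi, flag_artifact_epochs, load_events, load_recording
from eegrt.spectral import decompose_epochs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    for name in ("coupled", "null"):
        sess_dir = ROOT / "scratch" / f"session_{name}"
        rec = load_recording(sess_dir / "recording.csv", "csv")
        events = load_events(sess_dir / "events.csv")
        epochs = extract_tsi(rec, events, 64)
        flagged = flag_artifact_epochs(epochs, k=5.0)
        bands = decompose_epochs(epochs, pad_to=256)
        fm = build_feature_matrix(bands, events)
        out = ROOT / "scratch" / f"features_{name}.csv"
        feature_matrix_to_csv(fm, out)

        corr = np.array([
            abs(np.corrcoef(fm.values[:, j], fm.y)[0, 1])
            for j in range(fm.n_features)
        ])
        top = np.argsort(-corr)[:3]
        print(f"{name:8s}: {fm.n_trials} trials x {fm.n_features} features, "
              f"{int(flagged.sum())} epoch(s) amplitude-flagged -> {out}")
        print("         strongest |corr| with delay: "
              + ", ".join(f"{fm.column_labels[j]}={corr[j]:.2f}" for j in top))


if __name__ == "__main__":
    main()
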