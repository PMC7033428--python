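#!/usr/bin/env python
"""Statistical layer: delay summaries, robust trend, ANOVA, post-hoc t-tests.

For each session: summarize the reaction delays (min/median/max/sd, robust
delay-vs-time slope with its p-value) and compare the algorithms' pooled
absolute errors with a one-way ANOVA followed by pairwise Welch t-tests.
The SVR's selection-frequency table is also written.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from eegrt.io import load_events
from eegrt.prediction import EvalResult, RepResult, summarize_selected_features
from eegrt.stats import anova_oneway, pairwise_ttests, summarize_delays

ROOT = Path(__file__).resolve().parents[1]


def _load_eval(path: Path) -> EvalResult:
    raw = json.loads(path.read_text())
    per_rep = {}
    for alg, block in raw.items():
        per_rep[alg] = [
            RepResult(
                repetition=r["repetition"], seed=r["seed"],
                abs_errors=np.asarray(r["abs_errors_s"]), params=r["params"],
                selected_labels=r["selected_features"],
                test_trial_ids=np.asarray(r["test_trials"]),
            )
            for r in block["repetitions"]
        ]
    return EvalResult(per_rep=per_rep)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    results = ROOT / "results"
    for name in ("coupled", "null"):
        events = load_events(ROOT / "scratch" / f"session_{name}" / "events.csv")
        delays = summarize_delays(events)
        res = _load_eval(results / f"evaluation_{name}.json")

        groups = {a: res.pooled_abs_errors(a) for a in res.per_rep}
        f_stat, p_anova = anova_oneway(list(groups.values()))
        ttests = pairwise_ttests(groups)
        selection = summarize_selected_features(res)

        pd.DataFrame([delays.to_row()]).to_csv(
            results / f"delay_summary_{name}.csv", index=False)
        ttests.to_csv(results / f"pairwise_ttests_{name}.csv",
                      float_format="%.4g")
        selection.to_csv(results / f"selected_features_{name}.csv", index=False)
        (results / f"anova_{name}.json").write_text(
            json.dumps({"F": f_stat, "p": p_anova}, indent=1))

        print(f"{name} session: delays median {delays.median_s:.3f} s "
              f"(sd {delays.sd_s:.3f}), robust slope {delays.slope_s_per_s:.2e} s/s "
              f"(p={delays.slope_p:.3f}), n={delays.n_epochs}")
        print(f"  ANOVA across algorithms: F={f_stat:.3f}, p={p_anova:.3g}")
        pooled = selection[selection.subject == "all"].head(3)
        if not pooled.empty:
            tops = ", ".join(f"{r.feature} ({r['count']})"
                             for _, r in pooled.iterrows())
            print(f"  top pooled SVR selections: {tops}\n")


if __name__ == "__main__":
    main()
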