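#!/usr/bin/env python
"""Behavioral performance: outcome labeling, best-window d', lick profiles.

Labels every trial Hit/Miss/CR/FA from its response-window lick rate, scans
the sliding 150-trial window for the best d' (hit and correct-rejection
rates are reported on the same window), and bins lick probabilities per
0.1 s by stimulus and outcome.  Tables go to results/behavior/.
"""

import argparse

import pandas as pd

from common import RESULTS, labeled, load_or_simulate
from tpsd import behavior


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = RESULTS / "behavior"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for stage in ("learned", "naive"):
        bundle = load_or_simulate(stage, args.seed)
        outcomes = labeled(bundle)
        outcomes.to_csv(out / f"outcomes_{stage}.csv", index=False)
        m = behavior.best_window_dprime(outcomes, window=150)
        rows.append(
            {
                "stage": stage, "dprime": m.dprime, "hit_rate": m.hit_rate,
                "cr_rate": m.cr_rate, "window_start": m.window_start,
            }
        )
        verdict = "above" if m.dprime > behavior.LEARNING_THRESHOLD else "below"
        print(
            f"{stage:>7}: best-window d' = {m.dprime:.2f} "
            f"(Hr {m.hit_rate:.2f}, CRr {m.cr_rate:.2f}) -- {verdict} the "
            f"d' = 2 learning threshold"
        )
        prof = behavior.lick_probability_profile(
            bundle.licks, outcomes, ["stimulus", "outcome"], horizon=2.0
        )
        prof.to_csv(out / f"lick_probability_{stage}.csv", index=False)

    pd.DataFrame(rows).to_csv(out / "dprime_metrics.csv", index=False)
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
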