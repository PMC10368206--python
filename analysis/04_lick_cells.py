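#!/usr/bin/env python
"""Identify lick-modulated cells and check recovery against planted truth.

Inside the response window, forward sequential selection repeatedly picks
the cells most predictive of licked (Hit/FA) vs non-licked (CR/Miss) trials;
cells accrue control-referenced z-scored accuracies, the session is admitted
when score correlates with selection count, and cells >1 SD above the mean
score are flagged and removed from the sensory analyses.  Because the
fixture plants its lick-coupled cells, the flags can be scored against
ground truth.  Tables go to results/lick_cells/.
"""

import argparse

import numpy as np

from common import RESPONSE_WINDOW, RESULTS, labeled, load_or_simulate
from tpsd import lick_cells


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--machines", type=int, default=10)
    args = ap.parse_args()
    out = RESULTS / "lick_cells"
    out.mkdir(parents=True, exist_ok=True)

    bundle = load_or_simulate("learned", args.seed)
    outcomes = labeled(bundle)
    scores = lick_cells.score_cells(
        bundle.raster, outcomes, RESPONSE_WINDOW, n_select=20,
        n_machines=args.machines, seed=args.seed,
    )
    admission = lick_cells.admit_session(scores)
    flagged = lick_cells.flag_lick_cells(scores, admission)
    truth = set(np.flatnonzero(bundle.raster.lick_flags).tolist())

    table = scores.table.assign(
        flagged=scores.table["cell"].isin(flagged),
        planted=scores.table["cell"].isin(truth),
    )
    table.to_csv(out / "cell_scores.csv", index=False)

    sens = len(flagged & truth) / len(truth) if truth else float("nan")
    fp = len(flagged - truth) / (bundle.raster.n_cells - len(truth))
    print(
        f"session admitted: {admission.admitted} "
        f"(r = {admission.r:.2f}, p = {admission.p:.2g})"
    )
    print(
        f"flagged {len(flagged)} of {bundle.raster.n_cells} cells; "
        f"planted truth recovered with sensitivity {sens:.2f}, "
        f"false-flag rate {fp:.2f}"
    )
    cleaned = lick_cells.remove_cells(bundle.raster, flagged)
    cleaned.to_hdf5(out / "raster_nolick.h5")
    print(f"cleaned raster ({cleaned.n_cells} cells) written to {out}")


if __name__ == "__main__":
    main()
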