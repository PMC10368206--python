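#!/usr/bin/env python
"""Simulate one learned and one naive session of the temporal-pattern task.

Writes the trial schedules, 250 Hz lick trains, 15 Hz spike rasters and the
full parameter echo under results/fixtures/{learned,naive}/.  These fixtures
are the inputs to every later analysis step.
"""

import argparse

from common import FIXTURES, load_or_simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for stage in ("learned", "naive"):
        bundle = load_or_simulate(stage, args.seed)
        n_lick = int(bundle.raster.lick_flags.sum())
        print(
            f"{stage:>7}: {len(bundle.schedule)} trials "
            f"({(bundle.schedule['stimulus'] == 'P').sum()} preferred), "
            f"{len(bundle.licks)} licks, "
            f"{bundle.raster.n_cells} cells ({n_lick} planted lick-coupled) "
            f"-> {FIXTURES / stage}"
        )


if __name__ == "__main__":
    main()
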