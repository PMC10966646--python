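#!/usr/bin/env python
"""Compare initial-selection protocols under the fixed 360-compound budget.

Runs GP campaigns with the three initial-selection protocols (random-exploit,
random-explore-exploit, random-random-exploit) on each synthetic pool, three
seeds each, and tabulates final top-2%/5% Recall, F1 and Spearman rho.

Writes per-cycle aggregates to results/initial_selection_trajectories.csv and
the final-cycle comparison to results/initial_selection.csv.
"""

from pathlib import Path

import pandas as pd

from albench.driver import build_protocol, repeat_campaigns
from albench.synthetic import generate_library, scenario_preset

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PROTOCOLS = ("random-exploit", "random-explore-exploit", "random-random-exploit")
SEEDS = (1, 2, 3)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    finals, trajectories = [], []
    for pool_name in ("congeneric", "heterogeneous", "small-diverse"):
        pool = generate_library(scenario_preset(pool_name))
        for proto_name in PROTOCOLS:
            runs = repeat_campaigns(
                pool, build_protocol(proto_name), "gp", seeds=SEEDS
            )
            agg = runs.aggregate
            agg.insert(0, "protocol", proto_name)
            agg.insert(0, "pool", pool_name)
            trajectories.append(agg.round(4))
            last = agg.iloc[-1]
            finals.append(
                {
                    "pool": pool_name,
                    "protocol": proto_name,
                    "recall_top2": round(last["recall_top2_mean"], 3),
                    "recall_top5": round(last["recall_top5_mean"], 3),
                    "f1_top2": round(last["f1_top2_mean"], 3),
                    "spearman": round(last["spearman_mean"], 3),
                    "baseline_recall_top2": round(last["baseline_recall_top2_mean"], 3),
                }
            )
            print(
                f"{pool_name} / {proto_name}: final top-2% recall "
                f"{last['recall_top2_mean']:.3f} "
                f"(baseline {last['baseline_recall_top2_mean']:.3f})"
            )
    pd.DataFrame(finals).to_csv(RESULTS / "initial_selection.csv", index=False)
    pd.concat(trajectories, ignore_index=True).to_csv(
        RESULTS / "initial_selection_trajectories.csv", index=False
    )
    print(
        "a larger initial batch (120) trades early exploitation cycles for "
        "model quality; which wins depends on the pool's cluster structure"
    )


if __name__ == "__main__":
    main()
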