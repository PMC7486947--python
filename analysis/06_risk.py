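#!/usr/bin/env python
"""Summarize climate risk from the projection ensemble.

Reads results/mse_runs.csv (from 05_run_mse.py), computes the probability of
decline (>10%), severe decline (>50%) and collapse (>80%) in catch and
spawning biomass relative to the paired persistence runs over four
consecutive periods, and lists warm stanzas per scenario.  Writes
results/risk_table.csv.
"""

import pandas as pd

from beringmse import risk
from beringmse import synthetic as syn

IN, OUT = "results/mse_runs.csv", "results/risk_table.csv"


def main() -> None:
    results = pd.read_csv(IN)
    tables = []
    for metric in ("catch", "ssb"):
        sub = results if metric == "ssb" else results[results.variant != "no_fishing"]
        t = risk.risk_probability(sub, metric=metric)
        t.insert(0, "metric", metric)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT, index=False)

    show = table[(table.metric == "catch") & (table.threshold == "collapse")]
    print("P(catch collapse >80% vs persistence), by period:")
    print(
        show.pivot_table(
            index=["scenario", "species"], columns="period_start", values="probability"
        ).to_string(float_format=lambda v: f"{v:.2f}")
    )

    print("\nwarm stanzas (>2.1 C for >=5 consecutive years):")
    bundle = syn.make_study_fixture().forcing
    for name in ("mod_b", "high_b"):
        s = bundle[name]
        print(f"  {name}: {risk.detect_warm_stanzas(s.years, s.indices['bottom_temp'])}")
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
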