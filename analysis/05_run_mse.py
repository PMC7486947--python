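#!/usr/bin/env python
"""Run the closed-loop projection ensemble.

Couples forcing, recruitment, the operating model, the control rule and the
catch functions into the three-step annual loop under three management
variants (no fishing / control rule with catch = ABC / control rule with
catch functions and the 2 MT cap), over the persistence scenario plus one
moderate and one high warming trajectory.  Runs a desk-scale ensemble
(10 replicates per variant, full 2018-2100 horizon) and writes the long
results table to results/mse_runs.csv.
"""

import time

from beringmse import catchfn as cf
from beringmse import mse
from beringmse import opmodel as om
from beringmse import policy as pol
from beringmse import synthetic as syn

OUT = "results/mse_runs.csv"
SCENARIOS = ("persistence", "mod_b", "high_b")
N_REPS = 10  # desk-scale stand-in for the 100/30 replicate design
EXOGENOUS_TAC = 450_000.0  # rest of the managed complex, tons


def main() -> None:
    fixture = syn.make_study_fixture()
    pers = fixture.forcing["persistence"]
    _, b0 = om.project_unfished(
        fixture.species_cfgs, fixture.pred_cfg, fixture.true_recruitment, pers
    )
    f_target = pol.solve_F_target(
        fixture.species_cfgs, fixture.pred_cfg, fixture.true_recruitment, pers, b0,
        ("pollock", "pcod"), "arrowtooth", syn.ARROWTOOTH_HIST_F,
    )
    policy = pol.HarvestPolicy(b0=b0, f_target=f_target)
    setup = mse.MseSetup(
        fixture.species_cfgs, fixture.pred_cfg, policy,
        cf.fit_catch_functions(fixture.quota_history),
        exogenous_other_tac=EXOGENOUS_TAC,
        indicators={"a80": 1.0, "afa": 1.0},
    )
    t0 = time.time()
    results = mse.run_ensemble(
        [fixture.forcing[s] for s in SCENARIOS], setup, fixture.true_recruitment,
        variants=list(mse.Variant),
        n_reps={v: N_REPS for v in mse.Variant},
        base_seed=0,
    )
    results.to_csv(OUT, index=False)
    print(f"{len(results):,} rows in {time.time() - t0:.1f}s -> {OUT}")

    end = results[results.year >= 2080]
    summary = (
        end.groupby(["scenario", "variant", "species"])[["ssb", "catch"]]
        .mean()
        .unstack("scenario")
        .round(0)
    )
    print("\nmean 2080-2100 spawning biomass and catch (tons):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
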