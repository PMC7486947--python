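"""Closed-loop management strategy evaluation.

Each simulation year runs three steps: (1) advance the operating model one
year (climate-driven recruitment, weights and predation) and compute each
species' ABC from the sloping control rule against the climate-naive
reference points; (2) map ABC to TAC (identity for the uncapped variant; the
catch-function regressions plus proportional ecosystem cap for the capped
variant); (3) map TAC to realized catch, convert it to an effective fishing
mortality, remove it, and continue.

Uncertainty enters through recruitment: parameter replicates drawn from the
fitted coefficient covariance, and fresh lognormal process error each year.
Replicates are paired — a given replicate index uses the same parameter draw
and the same process-error sequence in every scenario and management variant,
so scenario-vs-persistence contrasts isolate the climate signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import catchfn
from .opmodel import (
    PredationConfig,
    SpeciesConfig,
    advance_year,
    baranov_catch,
    initial_state,
    natural_mortality,
    set_fishing,
    solve_F_from_catch,
)
from .policy import HarvestPolicy, compute_ABC, sloping_hcr
from .recruitment import RecruitmentModel, draw_parameter_replicates


class Variant(str, Enum):
    """Management variants: unfished baseline, control rule with catch = ABC,
    and control rule with the catch-function layer under the ecosystem cap."""

    NO_FISHING = "no_fishing"
    HCR_NO_CAP = "hcr_no_cap"
    HCR_WITH_CAP = "hcr_with_cap"


#: Replicate counts used for projection ensembles by variant.
DEFAULT_N_REPS = {
    Variant.NO_FISHING: 100,
    Variant.HCR_NO_CAP: 100,
    Variant.HCR_WITH_CAP: 30,
}


@dataclass
class MseSetup:
    """Everything a scenario run needs besides the forcing and the variant."""

    cfgs: dict[str, SpeciesConfig]
    pred_cfg: PredationConfig
    policy: HarvestPolicy
    catch_model: catchfn.CatchFunctionModel | None = None
    exogenous_other_tac: float = 0.0
    indicators: dict[str, float] | None = None


def _process_error(
    setup: MseSetup, n_years: int, replicate_seed: int
) -> dict[str, np.ndarray]:
    """Per-species standard-normal streams (scaled by each model's sigma at
    use), keyed only on the replicate seed so variants and scenarios share
    them."""
    rng = np.random.default_rng(replicate_seed)
    # sorted-species order keeps the stream independent of dict insertion order
    return {sp: rng.normal(0.0, 1.0, n_years) for sp in sorted(setup.cfgs)}


def run_scenario(
    forcing,
    setup: MseSetup,
    variant: Variant,
    recruit_models: dict[str, RecruitmentModel],
    seed: int,
    replicate_id: int = 0,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Run one closed-loop projection over all forcing years.

    Returns a long table with one row per species x year: recruitment (age-1
    numbers), spawning biomass, ABC, TAC, catch, realized F and the year's
    bottom temperature.  ``seed`` drives the process-error sequence;
    ``deterministic=True`` zeroes it.
    """
    variant = Variant(variant)
    years = forcing.years
    n_years = years.size
    std_norm = _process_error(setup, n_years, seed)
    indicators = setup.indicators or {}

    state = initial_state(setup.cfgs, forcing.year_slice(int(years[0])), int(years[0]))
    rows = []
    for i, y in enumerate(years):
        cov = forcing.year_slice(int(y))
        if i > 0:
            eps = {
                sp: (0.0 if deterministic else recruit_models[sp].sigma * std_norm[sp][i])
                for sp in setup.cfgs
            }
            state = advance_year(
                state, setup.cfgs, setup.pred_cfg, cov, recruit_models, eps=eps
            )
        ssb = state.ssb(setup.cfgs)
        if any(not np.isfinite(v) for v in ssb.values()):
            raise FloatingPointError(f"non-finite spawning biomass in year {int(y)}")

        if variant is Variant.NO_FISHING:
            abc = {sp: 0.0 for sp in setup.cfgs}
            tac = dict(abc)
            catch = dict(abc)
            f_real = {sp: 0.0 for sp in setup.cfgs}
        else:
            f_abc = {
                sp: sloping_hcr(setup.policy, ssb[sp], sp) for sp in setup.cfgs
            }
            abc = compute_ABC(state, setup.cfgs, f_abc)
            if variant is Variant.HCR_NO_CAP:
                tac = dict(abc)
                catch = dict(abc)
                f_real = dict(f_abc)
            else:
                if setup.catch_model is None:
                    raise ValueError("hcr_with_cap requires a fitted catch-function model")
                positive = {sp: v for sp, v in abc.items() if v > 0}
                tac = {sp: 0.0 for sp in setup.cfgs}
                catch = {sp: 0.0 for sp in setup.cfgs}
                if positive:
                    # regressions are defined for open fisheries only
                    tac_open = catchfn.predict_tac(
                        setup.catch_model,
                        {sp: positive.get(sp, 1.0) for sp in setup.catch_model.species},
                        indicators,
                    )
                    tac_open = {sp: v for sp, v in tac_open.items() if sp in positive}
                    tac_open = catchfn.apply_cap(
                        tac_open, setup.exogenous_other_tac, setup.policy.cap
                    )
                    catch_open = catchfn.predict_catch(
                        setup.catch_model,
                        {
                            sp: tac_open.get(sp, 1.0)
                            for sp in setup.catch_model.species
                        },
                        indicators,
                    )
                    for sp in positive:
                        tac[sp] = min(tac_open[sp], abc[sp])
                        catch[sp] = min(catch_open[sp], tac[sp])
                f_real = {}
                for sp, cfg in setup.cfgs.items():
                    m = natural_mortality(state, setup.cfgs, sp)
                    f_real[sp] = solve_F_from_catch(
                        state.n[sp], state.w[sp], cfg.selectivity, m, catch[sp]
                    )
            set_fishing(state, setup.cfgs, f_real)
            # realized catch after any F cap
            catch = {
                sp: baranov_catch(
                    state.n[sp], state.w[sp], setup.cfgs[sp].selectivity,
                    state.f[sp], state.z[sp],
                )
                for sp in setup.cfgs
            }

        for sp in setup.cfgs:
            rows.append(
                {
                    "variant": variant.value,
                    "scenario": forcing.scenario_id,
                    "replicate": replicate_id,
                    "species": sp,
                    "year": int(y),
                    "recruitment": float(state.n[sp][0]),
                    "ssb": ssb[sp],
                    "abc": abc[sp],
                    "tac": tac[sp],
                    "catch": catch[sp],
                    "f": state.f[sp],
                    "bottom_temp": cov["bottom_temp"],
                }
            )
    return pd.DataFrame(rows)


def run_ensemble(
    scenarios: list,
    setup: MseSetup,
    recruit_models: dict[str, RecruitmentModel],
    variants: list[Variant] | None = None,
    n_reps: dict[Variant, int] | None = None,
    base_seed: int = 0,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Replicate ensemble over scenarios x variants.

    Replicate r pairs a single recruitment-parameter draw and process-error
    stream across every scenario and variant; child seeds derive
    deterministically from ``base_seed``.  The persistence scenario must be
    present — it is the baseline all relative-change metrics divide by.
    """
    variants = [Variant(v) for v in (variants or list(Variant))]
    n_reps = {Variant(k): v for k, v in (n_reps or DEFAULT_N_REPS).items()}
    if not any(s.scenario_id == "persistence" for s in scenarios):
        raise ValueError("ensemble requires the persistence scenario")
    max_reps = max(n_reps.get(v, 1) for v in variants)

    rng = np.random.default_rng(base_seed)
    draws = {
        sp: (
            draw_parameter_replicates(m, max_reps, rng, positive=("beta0",))
            if m.cov is not None
            else [m] * max_reps
        )
        for sp, m in sorted(recruit_models.items())
    }
    rep_seeds = np.random.default_rng(base_seed + 1).integers(0, 2**31 - 1, size=max_reps)

    chunks = []
    for variant in variants:
        for r in range(n_reps.get(variant, 1)):
            models_r = {sp: draws[sp][r] for sp in recruit_models}
            for forcing in scenarios:
                chunks.append(
                    run_scenario(
                        forcing,
                        setup,
                        variant,
                        models_r,
                        seed=int(rep_seeds[r]),
                        replicate_id=r,
                        deterministic=deterministic,
                    )
                )
    return pd.concat(chunks, ignore_index=True)
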