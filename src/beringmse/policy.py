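"""Harvest policy: climate-naive reference points and the sloping control rule.

Reference points follow the regional tier-3 style procedure: B0 is the mean
unfished spawning biomass over an end-of-century window under the persistence
(climate-frozen) scenario, and F_target is the constant fishing mortality
whose window-mean spawning biomass equals 40% of B0.  The two gadids are
solved jointly (they interact through predation) with the flatfish F held at
its historical mean; the flatfish F_target is then solved with the gadid
rates fixed.

The annual control rule slopes F down between the target (40% B0) and an
ecosystem cutoff (20% B0), below which the fishery closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .opmodel import (
    PredationConfig,
    SpeciesConfig,
    baranov_catch,
    natural_mortality,
    project_constant_F,
)

#: Eastern-Bering-Sea-style ecosystem cap on summed TAC, tons.
DEFAULT_CAP = 2_000_000.0


class ReferencePointError(RuntimeError):
    """The iterative F_target solve could not meet its depletion target."""


@dataclass
class HarvestPolicy:
    """Per-species reference points plus control-rule shape parameters."""

    b0: dict[str, float]
    f_target: dict[str, float]
    cutoff_frac: float = 0.20
    target_frac: float = 0.40
    ref_window: tuple[int, int] = (2095, 2099)
    cap: float = DEFAULT_CAP
    hcr_form: str = "ramp_b0"  # or "tier3"
    tier3_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_frac < self.target_frac <= 1):
            raise ValueError("need 0 < cutoff_frac < target_frac <= 1")
        if any(v <= 0 for v in self.b0.values()):
            raise ValueError("B0 must be positive")
        if any(v < 0 for v in self.f_target.values()):
            raise ValueError("F_target must be non-negative")

    @property
    def b_target(self) -> dict[str, float]:
        return {sp: self.target_frac * b for sp, b in self.b0.items()}


def _window_depletion(traj, b0: dict[str, float], window) -> dict[str, float]:
    lo, hi = window
    sub = traj[(traj.year >= lo) & (traj.year <= hi)]
    mean_ssb = sub.groupby("species")["ssb"].mean()
    return {sp: float(mean_ssb[sp] / b0[sp]) for sp in b0}


def solve_F_target(
    cfgs: dict[str, SpeciesConfig],
    pred_cfg: PredationConfig,
    recruit_models,
    persistence_forcing,
    b0: dict[str, float],
    joint_species: tuple[str, str],
    fixed_species: str,
    fixed_species_hist_f: float,
    target_frac: float = 0.40,
    window: tuple[int, int] = (2095, 2099),
    tol: float = 1e-7,
    f_bracket: float = 3.0,
    max_rounds: int = 60,
) -> dict[str, float]:
    """Two-phase iterative solve for the target harvest rates.

    Phase 1 alternates single-species bisections for the two ``joint_species``
    (a damped fixed point; each inner solve holds the other species' F fixed)
    with ``fixed_species`` at its historical-mean F, until both window-mean
    depletions hit ``target_frac`` within ``tol``.  Phase 2 then solves
    ``fixed_species`` with the joint rates frozen.  The forcing must be the
    persistence scenario — reference points are climate-naive by construction.
    """
    if persistence_forcing.scenario_id != "persistence":
        raise ValueError("reference points are defined only under the persistence scenario")

    f = {sp: 0.0 for sp in cfgs}
    f[fixed_species] = fixed_species_hist_f

    def depletion_of(sp: str, f_try: float) -> float:
        f_all = dict(f)
        f_all[sp] = f_try
        traj = project_constant_F(cfgs, pred_cfg, recruit_models, persistence_forcing, f_all)
        return _window_depletion(traj, b0, window)[sp]

    def solve_one(sp: str) -> float:
        g = lambda x: depletion_of(sp, x) - target_frac
        g0 = g(0.0)
        if g0 < 0:
            raise ReferencePointError(
                f"{sp}: depletion {g0 + target_frac:.3f} at F=0 is already below the "
                f"{target_frac:.0%} target under persistence"
            )
        hi = f_bracket
        if g(hi) > 0:
            raise ReferencePointError(f"{sp}: depletion still above target at F={hi}")
        return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-14))

    # phase 1: alternate the two interacting species to a joint fixed point
    a, b = joint_species
    for _ in range(max_rounds):
        f[a] = solve_one(a)
        f[b] = solve_one(b)
        traj = project_constant_F(cfgs, pred_cfg, recruit_models, persistence_forcing, f)
        dep = _window_depletion(traj, b0, window)
        if abs(dep[a] - target_frac) < tol and abs(dep[b] - target_frac) < tol:
            break
    else:
        raise ReferencePointError(
            f"joint solve did not converge in {max_rounds} rounds; last depletions {dep}"
        )

    # phase 2: the remaining species, gadid rates frozen
    f[fixed_species] = solve_one(fixed_species)
    return f


def achieved_depletion(
    cfgs: dict[str, SpeciesConfig],
    pred_cfg: PredationConfig,
    recruit_models,
    persistence_forcing,
    b0: dict[str, float],
    f_target: dict[str, float],
    joint_species: tuple[str, str],
    fixed_species: str,
    fixed_species_hist_f: float,
    window: tuple[int, int] = (2095, 2099),
) -> dict[str, float]:
    """Window-mean depletion each solved F_target achieves under its own
    solve conditions.

    The joint species' depletions are evaluated with the remaining species at
    its historical-mean F (phase-1 conditions); the remaining species'
    depletion is evaluated with everything at F_target (phase-2 conditions).
    A converged solve returns target_frac for every species.
    """
    f1 = dict(f_target)
    f1[fixed_species] = fixed_species_hist_f
    t1 = project_constant_F(cfgs, pred_cfg, recruit_models, persistence_forcing, f1)
    d1 = _window_depletion(t1, b0, window)
    t2 = project_constant_F(cfgs, pred_cfg, recruit_models, persistence_forcing, f_target)
    d2 = _window_depletion(t2, b0, window)
    out = {sp: d1[sp] for sp in joint_species}
    out[fixed_species] = d2[fixed_species]
    return out


def sloping_hcr(policy: HarvestPolicy, b_now: float, species: str) -> float:
    """Annual control-rule F given start-of-year spawning biomass.

    F = F_target at or above 40% B0, 0 below the 20% B0 cutoff, and (default
    form) a straight line between the two breakpoints.  The ``tier3`` form
    uses F_target * (B/B40 - alpha)/(1 - alpha) on the ramp instead.
    """
    if b_now < 0:
        raise ValueError("spawning biomass must be >= 0")
    b0 = policy.b0[species]
    ft = policy.f_target[species]
    frac = b_now / b0
    if frac >= policy.target_frac:
        return ft
    if frac < policy.cutoff_frac:
        return 0.0
    if policy.hcr_form == "ramp_b0":
        return ft * (frac - policy.cutoff_frac) / (policy.target_frac - policy.cutoff_frac)
    if policy.hcr_form == "tier3":
        a = policy.tier3_alpha
        return max(0.0, ft * (frac / policy.target_frac - a) / (1.0 - a))
    raise ValueError(f"unknown hcr_form {policy.hcr_form!r}")


def compute_ABC(
    state,
    cfgs: dict[str, SpeciesConfig],
    f_abc: dict[str, float],
) -> dict[str, float]:
    """Acceptable biological catch per species: Baranov catch at F_ABC with
    Z = M1 + M2 + S*F_ABC on the current start-of-year state."""
    out = {}
    for sp, cfg in cfgs.items():
        f = float(f_abc[sp])
        if f < 0:
            raise ValueError("F_ABC must be >= 0")
        m = natural_mortality(state, cfgs, sp)
        z = m + cfg.selectivity * f
        out[sp] = baranov_catch(state.n[sp], state.w[sp], cfg.selectivity, f, z)
    return out
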