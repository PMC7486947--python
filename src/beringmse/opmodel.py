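"""Multispecies age-structured operating model.

Annual dynamics for a small groundfish complex: numbers-at-age survive
according to total mortality Z = M1 (residual natural) + M2 (predation)
+ S*F (fishing), cohorts shift one age with a plus group, and age-1
recruitment enters from the climate-enhanced Ricker model using last year's
spawning biomass and this year's environmental covariates.  Weight-at-age
responds multiplicatively to the bottom-temperature anomaly, and predation
mortality scales with predator biomass and temperature.  Catch is Baranov:

    C = sum_a (S_a F / Z_a) (1 - exp(-Z_a)) N_a W_a.

Units: numbers-at-age are thousands of fish and weights are kg, so N*W
products are metric tons directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .recruitment import RecruitmentModel, predict_recruitment

logger = logging.getLogger(__name__)

#: Hard upper bound on instantaneous fishing mortality when inverting catch.
F_MAX = 4.0

#: Multiplicative floor on the thermal weight response g(anomaly).
WEIGHT_FLOOR = 0.05


@dataclass
class SpeciesConfig:
    """Biology and fishery parameters for one species.

    ``thermal_weight_sens`` is the fractional change in weight-at-age per degC
    of bottom-temperature anomaly relative to ``ref_temp``.
    """

    name: str
    maturity: np.ndarray  # proportion mature at age, [0, 1]
    selectivity: np.ndarray  # fishery selectivity at age, [0, 1]
    m1: np.ndarray  # residual natural mortality at age, 1/yr
    base_weight: np.ndarray  # weight-at-age at zero anomaly, kg
    thermal_weight_sens: float = 0.0  # fraction per degC
    ref_temp: float = 1.2  # degC, anomaly reference
    init_recruits: float = 1e6  # thousands of age-1 fish used to seed projections

    def __post_init__(self) -> None:
        for attr in ("maturity", "selectivity", "m1", "base_weight"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        n = self.maturity.size
        if n < 2:
            raise ValueError("need at least 2 age classes")
        for attr in ("selectivity", "m1", "base_weight"):
            if getattr(self, attr).size != n:
                raise ValueError(f"{attr} length must match maturity ({n})")
        if np.any(self.m1 < 0) or np.any(self.base_weight <= 0):
            raise ValueError("M1 must be >= 0 and weights > 0")
        for attr in ("maturity", "selectivity"):
            v = getattr(self, attr)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{attr} must lie in [0, 1]")

    @property
    def n_ages(self) -> int:
        return int(self.maturity.size)


@dataclass
class PredationPair:
    """One predator->prey link of the simplified predation term."""

    predator: str
    prey: str
    coef: float  # 1/yr per ton of predator biomass, at zero anomaly
    temp_slope: float = 0.0  # per degC, exponential thermal scaling
    vulnerability: np.ndarray | None = None  # prey-age vulnerability, defaults to 1

    def __post_init__(self) -> None:
        if self.coef < 0:
            raise ValueError("predation coefficient must be >= 0")
        if self.vulnerability is not None:
            self.vulnerability = np.asarray(self.vulnerability, dtype=float)
            if np.any(self.vulnerability < 0) or np.any(self.vulnerability > 1):
                raise ValueError("vulnerability must lie in [0, 1]")


@dataclass
class PredationConfig:
    pairs: list[PredationPair] = field(default_factory=list)


@dataclass
class PopulationState:
    """Start-of-year snapshot: numbers, weights and mortality at age."""

    year: int
    n: dict[str, np.ndarray]  # thousands at age
    w: dict[str, np.ndarray]  # kg at age
    z: dict[str, np.ndarray]  # total mortality at age, 1/yr
    f: dict[str, float]  # fishing mortality applied this year

    def ssb(self, cfgs: dict[str, SpeciesConfig]) -> dict[str, float]:
        """Spawning biomass in tons: sum of maturity * N * W."""
        return {
            sp: float(np.sum(cfgs[sp].maturity * self.n[sp] * self.w[sp])) for sp in self.n
        }

    def biomass(self, sp: str) -> float:
        return float(np.sum(self.n[sp] * self.w[sp]))


def weight_at_age(cfg: SpeciesConfig, temp_anomaly: float) -> np.ndarray:
    """Realized weight-at-age W_a = Wbar_a * g(anomaly), with
    g(x) = 1 + sens * x clamped below at a small positive floor."""
    g = 1.0 + cfg.thermal_weight_sens * temp_anomaly
    if g < WEIGHT_FLOOR:
        logger.warning(
            "weight_at_age: thermal response clamped to floor %.2f for %s (anomaly %.2f)",
            WEIGHT_FLOOR, cfg.name, temp_anomaly,
        )
        g = WEIGHT_FLOOR
    return cfg.base_weight * g


def predation_mortality(
    pred_cfg: PredationConfig,
    cfgs: dict[str, SpeciesConfig],
    n: dict[str, np.ndarray],
    w: dict[str, np.ndarray],
    temp_anomaly: float = 0.0,
) -> dict[str, np.ndarray]:
    """Predation mortality M2 at age for every species.

    M2_{prey,a} = sum_predators coef * vuln_a * predator_biomass * h(anomaly)
    with h(x) = exp(temp_slope * x), so predation pressure rises with warming
    when temp_slope > 0 and is linear in predator biomass.
    """
    m2 = {sp: np.zeros(cfgs[sp].n_ages) for sp in cfgs}
    for pair in pred_cfg.pairs:
        if pair.predator not in cfgs or pair.prey not in cfgs:
            raise KeyError(f"unknown predation pair {pair.predator!r} -> {pair.prey!r}")
        bio_pred = float(np.sum(n[pair.predator] * w[pair.predator]))
        vuln = (
            pair.vulnerability
            if pair.vulnerability is not None
            else np.ones(cfgs[pair.prey].n_ages)
        )
        if vuln.size != cfgs[pair.prey].n_ages:
            raise ValueError(f"vulnerability length mismatch for prey {pair.prey!r}")
        m2[pair.prey] += pair.coef * vuln * bio_pred * np.exp(pair.temp_slope * temp_anomaly)
    return m2


def baranov_catch(
    n: np.ndarray, w: np.ndarray, sel: np.ndarray, f: float, z: np.ndarray
) -> float:
    """Baranov catch in N*W units (tons for thousands x kg)."""
    if f < 0:
        raise ValueError("F must be >= 0")
    if f == 0.0:
        return 0.0
    fished = sel * f > 0
    if np.any(fished & (z <= 0)):
        raise ZeroDivisionError("Z must be positive wherever S*F > 0")
    out = np.zeros_like(z)
    np.divide(sel * f, z, out=out, where=z > 0)
    return float(np.sum(out * (1.0 - np.exp(-z)) * n * w))


def solve_F_from_catch(
    n: np.ndarray,
    w: np.ndarray,
    sel: np.ndarray,
    m: np.ndarray,
    target_catch: float,
    rel_tol: float = 1e-8,
    f_max: float = F_MAX,
) -> float:
    """Effective F whose Baranov catch equals ``target_catch``.

    ``m`` is the non-fishing mortality at age (M1 + M2).  If the target
    exceeds the catch attainable at ``f_max``, F is capped there and the
    shortfall logged.
    """
    if target_catch < 0:
        raise ValueError("target catch must be >= 0")
    if target_catch == 0.0:
        return 0.0

    def catch_at(f: float) -> float:
        return baranov_catch(n, w, sel, f, m + sel * f)

    c_max = catch_at(f_max)
    if target_catch >= c_max:
        if target_catch > c_max:
            logger.warning(
                "solve_F_from_catch: target %.1f t exceeds attainable %.1f t; capping at F=%.1f",
                target_catch, c_max, f_max,
            )
        return f_max
    f = brentq(lambda x: catch_at(x) - target_catch, 0.0, f_max, xtol=1e-13, rtol=1e-14)
    assert abs(catch_at(f) - target_catch) <= rel_tol * target_catch
    return float(f)


def initial_state(
    cfgs: dict[str, SpeciesConfig],
    covariates: dict[str, float],
    year: int,
) -> PopulationState:
    """Seed state: M1-decayed age structure from each species' init_recruits."""
    n, w, z = {}, {}, {}
    for sp, cfg in cfgs.items():
        surv = np.exp(-np.cumsum(np.concatenate([[0.0], cfg.m1[:-1]])))
        n_a = cfg.init_recruits * surv
        # approximate plus-group accumulation at M1 of the last age
        n_a[-1] /= max(1.0 - np.exp(-cfg.m1[-1]), 1e-6)
        n[sp] = n_a
        w[sp] = weight_at_age(cfg, covariates["bottom_temp"] - cfg.ref_temp)
        z[sp] = cfg.m1.copy()
    state = PopulationState(year=year, n=n, w=w, z=z, f={sp: 0.0 for sp in cfgs})
    return state


def set_fishing(
    state: PopulationState, cfgs: dict[str, SpeciesConfig], f: dict[str, float]
) -> None:
    """Finalize this year's mortality by adding S*F on top of M1+M2 in place."""
    for sp, cfg in cfgs.items():
        f_sp = float(f.get(sp, 0.0))
        if f_sp < 0:
            raise ValueError("F must be >= 0")
        state.z[sp] = state.z[sp] - cfg.selectivity * state.f[sp] + cfg.selectivity * f_sp
        state.f[sp] = f_sp


def advance_year(
    state: PopulationState,
    cfgs: dict[str, SpeciesConfig],
    pred_cfg: PredationConfig,
    covariates: dict[str, float],
    recruit_models: dict[str, RecruitmentModel],
    eps: dict[str, float] | None = None,
    f_applied: dict[str, float] | None = None,
) -> PopulationState:
    """Advance the complex one year.

    Survivors move up one age under last year's Z (plus-group accumulates);
    age-1 recruits enter from last year's spawning biomass and this year's
    covariates; weights and predation mortality are recomputed at this year's
    temperature; Z is set to M1 + M2 + S*F with ``f_applied`` (default 0 —
    callers running a closed loop set F later via :func:`set_fishing`).
    """
    eps = eps or {}
    f_applied = f_applied or {}
    ssb_prev = state.ssb(cfgs)
    year = state.year + 1

    n_new: dict[str, np.ndarray] = {}
    for sp, cfg in cfgs.items():
        surv = state.n[sp] * np.exp(-state.z[sp])
        n_a = np.empty(cfg.n_ages)
        n_a[1:] = surv[:-1]
        n_a[-1] += surv[-1]  # plus group
        if ssb_prev[sp] <= 0:
            logger.warning("advance_year: %s spawning biomass is 0 in %d; no recruitment", sp, year - 1)
            n_a[0] = 0.0
        else:
            n_a[0] = predict_recruitment(
                recruit_models[sp], ssb_prev[sp], covariates, eps.get(sp, 0.0)
            )
        if np.any(n_a < 0) or np.any(~np.isfinite(n_a)):
            raise AssertionError(f"invalid numbers-at-age for {sp} in year {year}")
        n_new[sp] = n_a

    w_new = {
        sp: weight_at_age(cfg, covariates["bottom_temp"] - cfg.ref_temp)
        for sp, cfg in cfgs.items()
    }
    anomaly = covariates["bottom_temp"] - next(iter(cfgs.values())).ref_temp
    m2 = predation_mortality(pred_cfg, cfgs, n_new, w_new, anomaly)
    z_new = {}
    f_new = {}
    for sp, cfg in cfgs.items():
        f_sp = float(f_applied.get(sp, 0.0))
        z_new[sp] = cfg.m1 + m2[sp] + cfg.selectivity * f_sp
        f_new[sp] = f_sp
    return PopulationState(year=year, n=n_new, w=w_new, z=z_new, f=f_new)


def natural_mortality(
    state: PopulationState, cfgs: dict[str, SpeciesConfig], sp: str
) -> np.ndarray:
    """Non-fishing mortality at age (M1 + M2) implied by the state's Z and F."""
    return state.z[sp] - cfgs[sp].selectivity * state.f[sp]


def project_constant_F(
    cfgs: dict[str, SpeciesConfig],
    pred_cfg: PredationConfig,
    recruit_models: dict[str, RecruitmentModel],
    forcing,
    f: dict[str, float],
    eps: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Deterministic (or eps-driven) projection at constant per-species F over
    all forcing years.  Returns a long table (species, year, ssb, f, catch)."""
    years = forcing.years
    state = initial_state(cfgs, forcing.year_slice(int(years[0])), int(years[0]))
    set_fishing(state, cfgs, f)
    rows = []
    for i, y in enumerate(years):
        if i > 0:
            eps_y = {sp: float(eps[sp][i]) for sp in cfgs} if eps else None
            state = advance_year(
                state, cfgs, pred_cfg, forcing.year_slice(int(y)), recruit_models,
                eps=eps_y, f_applied=f,
            )
        ssb = state.ssb(cfgs)
        for sp, cfg in cfgs.items():
            rows.append(
                {
                    "species": sp,
                    "year": int(y),
                    "ssb": ssb[sp],
                    "f": state.f[sp],
                    "catch": baranov_catch(
                        state.n[sp], state.w[sp], cfg.selectivity, state.f[sp], state.z[sp]
                    ),
                }
            )
    return pd.DataFrame(rows)


def project_unfished(
    cfgs: dict[str, SpeciesConfig],
    pred_cfg: PredationConfig,
    recruit_models: dict[str, RecruitmentModel],
    forcing,
    window: tuple[int, int] = (2095, 2099),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Project with F = 0 throughout and return (trajectory, B0 per species),
    B0 being mean spawning biomass over the inclusive year ``window``."""
    lo, hi = window
    if lo < forcing.years[0] or hi > forcing.years[-1]:
        raise ValueError(f"window {window} outside projection years")
    traj = project_constant_F(
        cfgs, pred_cfg, recruit_models, forcing, {sp: 0.0 for sp in cfgs}
    )
    sub = traj[(traj.year >= lo) & (traj.year <= hi)]
    b0 = sub.groupby("species")["ssb"].mean().to_dict()
    return traj, b0
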