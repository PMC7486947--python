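"""Synthetic study fixture: every input the pipeline needs, generated with
the statistical structure the analysis assumes.

The fixture emulates, at desk scale, the data flows of a Bering-Sea-style
climate-to-fish-to-fisheries coupling: a hindcast plus an ensemble of
warming trajectories (two emissions-like tiers x three model-like variants),
three interacting groundfish species with known ("true") climate-enhanced
recruitment parameters — warming and cold-pool loss depress recruitment,
large zooplankton supports it — and a 1992-2017-style quota history drawn
from known log-linear TAC/catch relationships with correlated lognormal
noise.  Because every generating parameter is known, fitting code can be
validated against truth, and with a fixed seed every artefact is
byte-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forcing as fc
from .catchfn import QuotaRecord
from .opmodel import PredationConfig, PredationPair, SpeciesConfig
from .recruitment import DEFAULT_COVARIATES, RecruitmentModel, RecruitObservation, predict_recruitment

SPECIES = ("pollock", "pcod", "arrowtooth")


# ---------------------------------------------------------------------------
# species biology


def make_species_configs() -> tuple[dict[str, SpeciesConfig], PredationConfig]:
    """Three species loosely shaped like a gadid pair plus a flatfish:
    10-12 ages, near-knife-edge maturity, dome-free selectivity, and mild
    temperature-sensitive predation of the gadids on juvenile pollock."""

    def ramp(n, a50, width):
        ages = np.arange(1, n + 1)
        return 1.0 / (1.0 + np.exp(-(ages - a50) / width))

    pollock = SpeciesConfig(
        name="pollock",
        maturity=ramp(10, 4.0, 0.6),
        selectivity=ramp(10, 4.5, 0.7),
        m1=np.array([0.9, 0.45, 0.35, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3]),
        base_weight=np.array([0.05, 0.25, 0.45, 0.65, 0.85, 1.0, 1.15, 1.25, 1.35, 1.45]),
        thermal_weight_sens=-0.03,
        init_recruits=8e6,
    )
    pcod = SpeciesConfig(
        name="pcod",
        maturity=ramp(12, 5.0, 0.7),
        selectivity=ramp(12, 5.5, 0.8),
        m1=np.concatenate([[0.6, 0.45], np.full(10, 0.37)]),
        base_weight=0.2 + 0.75 * np.arange(1, 13),
        thermal_weight_sens=-0.025,
        init_recruits=4e5,
    )
    arrowtooth = SpeciesConfig(
        name="arrowtooth",
        maturity=ramp(12, 6.0, 0.9),
        selectivity=ramp(12, 6.5, 1.0),
        m1=np.concatenate([[0.5, 0.35], np.full(10, 0.25)]),
        base_weight=0.1 + 0.28 * np.arange(1, 13),
        thermal_weight_sens=-0.015,
        init_recruits=3e5,
    )
    cfgs = {c.name: c for c in (pollock, pcod, arrowtooth)}

    pred_cfg = PredationConfig(
        pairs=[
            PredationPair(
                predator="pcod", prey="pollock", coef=4e-8, temp_slope=0.12,
                vulnerability=np.array([1.0, 0.6, 0.3, 0.1, 0, 0, 0, 0, 0, 0]),
            ),
            PredationPair(
                predator="arrowtooth", prey="pollock", coef=5e-8, temp_slope=0.12,
                vulnerability=np.array([1.0, 0.7, 0.3, 0.1, 0, 0, 0, 0, 0, 0]),
            ),
        ]
    )
    return cfgs, pred_cfg


def spawners_per_recruit(cfg: SpeciesConfig, f: float = 0.0) -> float:
    """Equilibrium spawning biomass (tons) per unit age-1 recruit at constant
    F, M1 only (no predation), with plus-group accumulation."""
    z = cfg.m1 + cfg.selectivity * f
    n = np.empty(cfg.n_ages)
    n[0] = 1.0
    for a in range(1, cfg.n_ages):
        n[a] = n[a - 1] * np.exp(-z[a - 1])
    n[-1] /= max(1.0 - np.exp(-z[-1]), 1e-12)
    return float(np.sum(cfg.maturity * n * cfg.base_weight))


#: log-scale covariate effects per species: warming and cold-pool loss hurt,
#: zooplankton helps; the flatfish is least climate-sensitive.
TRUE_COVARIATE_EFFECTS = {
    "pollock": {"bottom_temp": -0.28, "cold_pool": 0.35, "zoop_spring": 0.025, "zoop_fall": 0.055},
    "pcod": {"bottom_temp": -0.22, "cold_pool": 0.30, "zoop_spring": 0.020, "zoop_fall": 0.040},
    "arrowtooth": {"bottom_temp": -0.10, "cold_pool": 0.10, "zoop_spring": 0.010, "zoop_fall": 0.020},
}

#: residual recruitment SD (log scale) per species.
TRUE_SIGMA = {"pollock": 0.55, "pcod": 0.45, "arrowtooth": 0.35}

#: equilibrium "replacement" log-productivity and target unfished spawning
#: biomass (tons) used to place alpha and beta0 on realistic scales.
_PRODUCTIVITY = {"pollock": 1.5, "pcod": 1.2, "arrowtooth": 1.0}
_B0_SCALE = {"pollock": 16.0e6, "pcod": 2.0e6, "arrowtooth": 1.2e6}

#: historical-mean flatfish fishing mortality (well below its F40 proxy).
ARROWTOOTH_HIST_F = 0.05


def baseline_covariates(gen_cfg: fc.ForcingGeneratorConfig | None = None) -> dict[str, float]:
    cfg = gen_cfg or default_forcing_config()
    return {
        "bottom_temp": cfg.base_temp,
        "cold_pool": cfg.cold_pool_base,
        "zoop_spring": cfg.zoop_base,
        "zoop_fall": cfg.zoop_base,
    }


def true_recruitment_models(
    cfgs: dict[str, SpeciesConfig] | None = None,
    gen_cfg: fc.ForcingGeneratorConfig | None = None,
) -> dict[str, RecruitmentModel]:
    """Generating recruitment parameters, placed so each species' unfished
    equilibrium sits near its target scale under baseline climate."""
    cfgs = cfgs or make_species_configs()[0]
    xbar = baseline_covariates(gen_cfg)
    out = {}
    for sp, cfg in cfgs.items():
        betas = TRUE_COVARIATE_EFFECTS[sp]
        bx = sum(betas[c] * xbar[c] for c in betas)
        phi0 = spawners_per_recruit(cfg)
        beta0 = _PRODUCTIVITY[sp] / _B0_SCALE[sp]
        alpha = _PRODUCTIVITY[sp] - bx - np.log(phi0)
        out[sp] = RecruitmentModel(
            alpha=float(alpha),
            beta0=float(beta0),
            betas=dict(betas),
            sigma=TRUE_SIGMA[sp],
            covariate_names=DEFAULT_COVARIATES,
        )
    return out


# ---------------------------------------------------------------------------
# forcing


def default_forcing_config(seed: int = 0) -> fc.ForcingGeneratorConfig:
    """Hindcast 1979-2017 plus six warming trajectories, 2006-2100: a
    moderate tier warming ~1-2.5 degC and a high tier ~2-4.5 degC over the
    roughly 80-year projection, three trajectory variants each."""
    scenarios = [
        fc.ScenarioSpec("mod_a", warming_rate=0.016, temp_offset=0.25),
        fc.ScenarioSpec("mod_b", warming_rate=0.022, temp_offset=-0.15),
        fc.ScenarioSpec("mod_c", warming_rate=0.027, temp_offset=0.10),
        fc.ScenarioSpec("high_a", warming_rate=0.030, temp_offset=0.20),
        fc.ScenarioSpec("high_b", warming_rate=0.040, temp_offset=-0.10),
        fc.ScenarioSpec("high_c", warming_rate=0.050, temp_offset=0.15),
    ]
    return fc.ForcingGeneratorConfig(scenarios=scenarios, seed=seed)


def make_forcing_bundle(
    seed: int = 0,
    gen_cfg: fc.ForcingGeneratorConfig | None = None,
    bc_cfg: fc.BiasCorrectionConfig | None = None,
    projection_start: int = 2018,
) -> dict[str, fc.ClimateIndexSeries]:
    """Hindcast, bias-corrected projections restricted to the projection
    years, and the persistence counterfactual, keyed by scenario id."""
    gen_cfg = gen_cfg or default_forcing_config(seed)
    bc_cfg = bc_cfg or fc.BiasCorrectionConfig()
    raw = fc.generate_forcing(gen_cfg)
    hind = raw[0]
    proj_years = np.arange(projection_start, gen_cfg.projection_end + 1)
    out = {"hindcast": hind}
    for series in raw[1:]:
        corr = fc.bias_correct(series, hind, bc_cfg)
        mask = np.isin(corr.years, proj_years)
        out[series.scenario_id] = fc.ClimateIndexSeries(
            corr.scenario_id, corr.years[mask], {k: v[mask] for k, v in corr.indices.items()}
        )
    out["persistence"] = fc.make_persistence(hind, bc_cfg, proj_years)
    return out


# ---------------------------------------------------------------------------
# recruitment observations


def make_recruit_observations(
    models: dict[str, RecruitmentModel],
    hindcast: fc.ClimateIndexSeries,
    seed: int = 0,
    noise: bool = True,
) -> dict[str, list[RecruitObservation]]:
    """Hindcast-period spawner/recruit pairs generated exactly from the
    climate-enhanced Ricker model.

    Spawning biomass follows a seeded lognormal random walk around half the
    species' unfished scale (the fit only needs contrast in B, not coupled
    population dynamics)."""
    rng = np.random.default_rng(seed)
    out = {}
    for sp in sorted(models):
        m = models[sp]
        b_mid = 0.5 * _B0_SCALE[sp]
        log_b = np.log(b_mid) + np.cumsum(rng.normal(0, 0.45, hindcast.years.size))
        log_b -= log_b.mean() - np.log(b_mid)
        obs = []
        for i, y in enumerate(hindcast.years):
            cov = hindcast.year_slice(int(y))
            eps = rng.normal(0, m.sigma) if noise else 0.0
            r = predict_recruitment(m, float(np.exp(log_b[i])), cov, eps)
            obs.append(
                RecruitObservation(
                    year=int(y),
                    spawning_biomass=float(np.exp(log_b[i])),
                    recruitment=r,
                    covariates={c: cov[c] for c in m.covariate_names},
                )
            )
        out[sp] = obs
    return out


# ---------------------------------------------------------------------------
# quota history


@dataclass
class TrueCatchFunctionParams:
    """Generating coefficients of the quota-history regressions."""

    tac_intercept: dict[str, float]
    tac_own: dict[str, float]
    tac_cross: dict[str, dict[str, float]]
    catch_intercept: dict[str, float]
    catch_own: dict[str, float]
    catch_cross: dict[str, dict[str, float]]
    indicator_effects: dict[str, dict[str, float]]
    tac_sd: float = 0.10
    catch_sd: float = 0.07
    resid_corr: float = 0.5


def true_catch_function_params() -> TrueCatchFunctionParams:
    zero_cross = {sp: {o: 0.0 for o in SPECIES if o != sp} for sp in SPECIES}
    cross = {
        sp: {o: -4e-8 for o in SPECIES if o != sp} for sp in SPECIES
    }
    return TrueCatchFunctionParams(
        tac_intercept={"pollock": 0.45, "pcod": 0.30, "arrowtooth": -0.20},
        tac_own={sp: 0.96 for sp in SPECIES},
        tac_cross=cross,
        catch_intercept={"pollock": np.log(0.97), "pcod": np.log(0.92), "arrowtooth": np.log(0.80)},
        catch_own={sp: 1.0 for sp in SPECIES},
        catch_cross=zero_cross,
        indicator_effects={
            sp: {"a80": 0.04, "afa": 0.03} for sp in SPECIES
        },
    )


#: mean historical ABC scale per species, tons.
ABC_SCALE = {"pollock": 1.6e6, "pcod": 3.0e5, "arrowtooth": 1.2e5}


def make_quota_history(
    seed: int = 0,
    years: tuple[int, int] = (1992, 2017),
    params: TrueCatchFunctionParams | None = None,
    abc_sd: float = 0.30,
) -> list[QuotaRecord]:
    """1992-2017-style ABC/TAC/catch records from the true log-linear
    relationships with cross-species-correlated lognormal noise."""
    p = params or true_catch_function_params()
    rng = np.random.default_rng(seed)
    yrs = np.arange(years[0], years[1] + 1)
    k = len(SPECIES)
    corr = np.full((k, k), p.resid_corr) + (1 - p.resid_corr) * np.eye(k)
    chol = np.linalg.cholesky(corr)

    records = []
    for y in yrs:
        indicators = {"a80": float(y >= 2008), "afa": float(y >= 1999)}
        abc = {
            sp: ABC_SCALE[sp] * float(np.exp(rng.normal(0, abc_sd)))
            for sp in SPECIES
        }
        e_tac = p.tac_sd * (chol @ rng.normal(size=k))
        e_c = p.catch_sd * (chol @ rng.normal(size=k))
        tac, catch = {}, {}
        for i, sp in enumerate(SPECIES):
            lin = p.tac_intercept[sp] + p.tac_own[sp] * np.log(abc[sp])
            lin += sum(c * abc[o] for o, c in p.tac_cross[sp].items())
            lin += sum(
                p.indicator_effects[sp][name] * val for name, val in indicators.items()
            )
            tac[sp] = min(float(np.exp(lin + e_tac[i])), abc[sp])
        for i, sp in enumerate(SPECIES):
            lin = p.catch_intercept[sp] + p.catch_own[sp] * np.log(tac[sp])
            lin += sum(c * tac[o] for o, c in p.catch_cross[sp].items())
            lin += sum(
                p.indicator_effects[sp][name] * val for name, val in indicators.items()
            )
            catch[sp] = min(float(np.exp(lin + e_c[i])), tac[sp])
        records.append(QuotaRecord(year=int(y), abc=abc, tac=tac, catch=catch, indicators=indicators))
    return records


# ---------------------------------------------------------------------------
# the bundled fixture


@dataclass
class StudyEmulationConfig:
    seed: int = 0
    hindcast_span: tuple[int, int] = (1979, 2017)
    projection_span: tuple[int, int] = (2018, 2100)
    quota_span: tuple[int, int] = (1992, 2017)
    ref_span: tuple[int, int] = (2006, 2017)

    def __post_init__(self) -> None:
        if not (
            self.hindcast_span[0] <= self.ref_span[0]
            and self.ref_span[1] <= self.hindcast_span[1]
            and self.projection_span[0] == self.hindcast_span[1] + 1
        ):
            raise ValueError("inconsistent year spans")


@dataclass
class StudyFixture:
    """Everything the pipeline consumes, generated from known truth."""

    cfg: StudyEmulationConfig
    species_cfgs: dict[str, SpeciesConfig]
    pred_cfg: PredationConfig
    forcing: dict[str, fc.ClimateIndexSeries]
    true_recruitment: dict[str, RecruitmentModel]
    recruit_obs: dict[str, list[RecruitObservation]]
    quota_history: list[QuotaRecord]
    true_catch_params: TrueCatchFunctionParams
    arrowtooth_hist_f: float = ARROWTOOTH_HIST_F


def make_study_fixture(cfg: StudyEmulationConfig | None = None) -> StudyFixture:
    """Build the full fixture; same seed, same bytes."""
    cfg = cfg or StudyEmulationConfig()
    gen_cfg = default_forcing_config(cfg.seed)
    gen_cfg.hindcast_start, gen_cfg.hindcast_end = cfg.hindcast_span
    gen_cfg.projection_end = cfg.projection_span[1]
    bc_cfg = fc.BiasCorrectionConfig(ref_start=cfg.ref_span[0], ref_end=cfg.ref_span[1])
    species_cfgs, pred_cfg = make_species_configs()
    forcing_bundle = make_forcing_bundle(
        cfg.seed, gen_cfg, bc_cfg, projection_start=cfg.projection_span[0]
    )
    models = true_recruitment_models(species_cfgs, gen_cfg)
    obs = make_recruit_observations(models, forcing_bundle["hindcast"], seed=cfg.seed + 1)
    history = make_quota_history(seed=cfg.seed + 2, years=cfg.quota_span)
    return StudyFixture(
        cfg=cfg,
        species_cfgs=species_cfgs,
        pred_cfg=pred_cfg,
        forcing=forcing_bundle,
        true_recruitment=models,
        recruit_obs=obs,
        quota_history=history,
        true_catch_params=true_catch_function_params(),
    )


# ---------------------------------------------------------------------------
# toy worked example


def make_toy_worked_example() -> StudyFixture:
    """Tiny 3-species, 5-age, 10-year bundle for hand-checkable dynamics.

    A synthetic miniature (not a condensed version of any real assessment):
    flat mortality and selectivity, simple weights, constant climate, no
    predation — every update is reproducible with a hand calculator or the
    spreadsheet-style oracle in the test suite.
    """
    def cfg(name, m, w0, init):
        return SpeciesConfig(
            name=name,
            maturity=np.array([0.0, 0.5, 1.0, 1.0, 1.0]),
            selectivity=np.array([0.0, 0.5, 1.0, 1.0, 1.0]),
            m1=np.full(5, m),
            base_weight=w0 * np.arange(1, 6, dtype=float),
            thermal_weight_sens=0.0,
            init_recruits=init,
        )

    cfgs = {
        "pollock": cfg("pollock", 0.3, 0.2, 1000.0),
        "pcod": cfg("pcod", 0.35, 0.5, 300.0),
        "arrowtooth": cfg("arrowtooth", 0.25, 0.3, 200.0),
    }
    years = np.arange(2001, 2011)
    const = fc.ClimateIndexSeries(
        "persistence",
        years,
        {
            "bottom_temp": np.full(years.size, 1.2),
            "cold_pool": np.full(years.size, 0.5),
            "zoop_spring": np.full(years.size, 10.0),
            "zoop_fall": np.full(years.size, 10.0),
        },
    )
    models = {
        sp: RecruitmentModel(
            alpha=1.0, beta0=1e-3, betas={}, sigma=0.0, covariate_names=DEFAULT_COVARIATES
        )
        for sp in cfgs
    }
    toy_cfg = StudyEmulationConfig()
    return StudyFixture(
        cfg=toy_cfg,
        species_cfgs=cfgs,
        pred_cfg=PredationConfig(),
        forcing={"persistence": const},
        true_recruitment=models,
        recruit_obs={},
        quota_history=make_quota_history(seed=123, years=(1998, 2010)),
        true_catch_params=true_catch_function_params(),
    )
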