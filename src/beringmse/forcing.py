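"""Synthetic climate-index forcing: generation, delta-method bias correction,
and the persistence (climate-frozen) counterfactual.

Each scenario is an annual series of shelf-wide environmental covariates —
summer bottom temperature (degC), cold-pool areal fraction, and spring/fall
large-zooplankton indices — the covariates the recruitment model consumes.
Projection scenarios are bias-corrected to a hindcast reference period
(default 2006-2017) with the delta method under unequal variances:

    T'_fut,y = mean(hind, ref) + sd(hind, ref)/sd(fut, ref) * (T_fut,y - mean(fut, ref))

so that over the reference years the corrected series reproduces the hindcast
mean and standard deviation exactly.  Sample standard deviations use the n-1
denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Covariate names every series carries, in canonical order.
INDEX_NAMES = ("bottom_temp", "cold_pool", "zoop_spring", "zoop_fall")

#: Indices with hard physical bounds enforced after bias correction.
BOUNDED_INDICES = {"cold_pool": (0.0, 1.0)}


class ForcingError(ValueError):
    """Configuration or alignment problem in a forcing operation."""


@dataclass
class ClimateIndexSeries:
    """Annual environmental-covariate series for one climate scenario."""

    scenario_id: str
    years: np.ndarray
    indices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.indices = {k: np.asarray(v, dtype=float) for k, v in self.indices.items()}
        if self.years.size == 0:
            raise ForcingError("series must contain at least one year")
        if not np.all(np.diff(self.years) == 1):
            raise ForcingError("years must be contiguous and strictly increasing")
        for name, vec in self.indices.items():
            if vec.shape != self.years.shape:
                raise ForcingError(
                    f"index {name!r} has length {vec.size}, expected {self.years.size}"
                )
        cp = self.indices.get("cold_pool")
        if cp is not None and (np.any(cp < 0) or np.any(cp > 1)):
            raise ForcingError("cold_pool values must lie in [0, 1]")

    def year_slice(self, year: int) -> dict[str, float]:
        """Covariate values for a single year, as a plain mapping."""
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise ForcingError(f"year {year} not in scenario {self.scenario_id!r}")
        return {k: float(v[idx[0]]) for k, v in self.indices.items()}

    def contains_years(self, years: np.ndarray) -> bool:
        return bool(np.all(np.isin(years, self.years)))

    def to_frame(self):
        """Long-format table: scenario, year, index_name, value."""
        import pandas as pd

        rows = []
        for name, vec in self.indices.items():
            rows.append(
                pd.DataFrame(
                    {
                        "scenario": self.scenario_id,
                        "year": self.years,
                        "index_name": name,
                        "value": vec,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df, scenario_id: str) -> "ClimateIndexSeries":
        sub = df[df["scenario"] == scenario_id]
        if sub.empty:
            raise ForcingError(f"scenario {scenario_id!r} absent from table")
        wide = sub.pivot(index="year", columns="index_name", values="value").sort_index()
        years = wide.index.to_numpy(dtype=int)
        return cls(scenario_id, years, {c: wide[c].to_numpy() for c in wide.columns})


@dataclass
class BiasCorrectionConfig:
    """Reference period and numerical guard for the delta-method correction."""

    ref_start: int = 2006
    ref_end: int = 2017
    min_sd: float = 1e-8

    @property
    def ref_years(self) -> np.ndarray:
        if self.ref_end < self.ref_start:
            raise ForcingError("ref_end must be >= ref_start")
        return np.arange(self.ref_start, self.ref_end + 1)


@dataclass
class ScenarioSpec:
    """One projection trajectory: a linear warming trend plus interannual noise."""

    name: str
    warming_rate: float  # degC per year
    temp_offset: float = 0.0  # raw model bias vs hindcast baseline, degC
    freeze_after: int | None = None  # hold conditions at this year's trend level


@dataclass
class ForcingGeneratorConfig:
    """Synthetic stand-in for an ensemble of downscaled ocean-model runs.

    A hindcast plus one raw projection per scenario, overlapping on the
    bias-correction reference years.  Zooplankton indices co-vary negatively
    with temperature by default (warm years carry less large, lipid-rich
    zooplankton), and the cold-pool fraction shrinks as the shelf warms.
    """

    hindcast_start: int = 1979
    hindcast_end: int = 2017
    projection_start: int = 2006
    projection_end: int = 2100
    base_temp: float = 1.2  # degC, long-term hindcast mean bottom temperature
    hindcast_trend: float = 0.012  # degC/yr secular trend in the hindcast
    temp_noise_sd: float = 0.45  # degC interannual variability
    zoop_base: float = 10.0
    zoop_temp_slope: float = -1.6  # index units per degC anomaly
    zoop_noise_sd: float = 0.8
    cold_pool_base: float = 0.55
    cold_pool_temp_slope: float = -0.12  # fraction per degC anomaly
    cold_pool_noise_sd: float = 0.04
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hindcast_end < self.hindcast_start or self.projection_end < self.projection_start:
            raise ForcingError("year spans must be non-empty")
        if self.temp_noise_sd < 0 or self.zoop_noise_sd < 0 or self.cold_pool_noise_sd < 0:
            raise ForcingError("noise SDs must be non-negative")


def _derive_indices(
    cfg: ForcingGeneratorConfig, temp: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Build zooplankton and cold-pool series from a realized temperature series."""
    anom = temp - cfg.base_temp
    n = temp.size
    zs = cfg.zoop_base + cfg.zoop_temp_slope * anom + rng.normal(0, cfg.zoop_noise_sd, n)
    zf = cfg.zoop_base + cfg.zoop_temp_slope * anom + rng.normal(0, cfg.zoop_noise_sd, n)
    cp = cfg.cold_pool_base + cfg.cold_pool_temp_slope * anom
    cp = np.clip(cp + rng.normal(0, cfg.cold_pool_noise_sd, n), 0.0, 1.0)
    return {"bottom_temp": temp, "cold_pool": cp, "zoop_spring": zs, "zoop_fall": zf}


def generate_forcing(cfg: ForcingGeneratorConfig) -> list[ClimateIndexSeries]:
    """Generate the hindcast plus one raw projection series per scenario.

    Returns the hindcast first (scenario_id "hindcast").  Projections overlap
    the hindcast on the reference years and continue beyond its end; with a
    fixed seed the output is bit-identical across calls.
    """
    rng = np.random.default_rng(cfg.seed)

    hy = np.arange(cfg.hindcast_start, cfg.hindcast_end + 1)
    h_temp = (
        cfg.base_temp
        + cfg.hindcast_trend * (hy - hy.mean())
        + rng.normal(0, cfg.temp_noise_sd, hy.size)
    )
    out = [ClimateIndexSeries("hindcast", hy, _derive_indices(cfg, h_temp, rng))]

    py = np.arange(cfg.projection_start, cfg.projection_end + 1)
    for spec in cfg.scenarios:
        t_elapsed = (py - cfg.projection_start).astype(float)
        if spec.freeze_after is not None:
            t_elapsed = np.minimum(t_elapsed, spec.freeze_after - cfg.projection_start)
        trend = cfg.base_temp + spec.temp_offset + spec.warming_rate * t_elapsed
        temp = trend + rng.normal(0, cfg.temp_noise_sd, py.size)
        out.append(ClimateIndexSeries(spec.name, py, _derive_indices(cfg, temp, rng)))
    return out


def bias_correct(
    fut: ClimateIndexSeries,
    hind: ClimateIndexSeries,
    cfg: BiasCorrectionConfig | None = None,
) -> ClimateIndexSeries:
    """Delta-method bias correction of a projection against the hindcast.

    Each index is corrected independently on its raw scale; bounded indices
    (cold-pool fraction) are clipped back into their physical range afterwards,
    with clips logged.  Over the reference years the corrected series matches
    the hindcast reference mean and SD exactly (n-1 denominator).
    """
    cfg = cfg or BiasCorrectionConfig()
    ref = cfg.ref_years
    for series, label in ((fut, "projection"), (hind, "hindcast")):
        if not series.contains_years(ref):
            raise ForcingError(
                f"{label} {series.scenario_id!r} does not cover reference years "
                f"{cfg.ref_start}-{cfg.ref_end}"
            )
    fut_ref_mask = np.isin(fut.years, ref)
    hind_ref_mask = np.isin(hind.years, ref)

    corrected: dict[str, np.ndarray] = {}
    for name, vec in fut.indices.items():
        if name not in hind.indices:
            raise ForcingError(f"hindcast lacks index {name!r}")
        hind_ref = hind.indices[name][hind_ref_mask]
        fut_ref = vec[fut_ref_mask]
        sd_fut = float(np.std(fut_ref, ddof=1))
        if sd_fut <= cfg.min_sd:
            raise ForcingError(
                f"projection reference-period SD for {name!r} is degenerate ({sd_fut:g})"
            )
        sd_hind = float(np.std(hind_ref, ddof=1))
        adj = float(np.mean(hind_ref)) + (sd_hind / sd_fut) * (vec - float(np.mean(fut_ref)))
        if name in BOUNDED_INDICES:
            lo, hi = BOUNDED_INDICES[name]
            n_clip = int(np.sum((adj < lo) | (adj > hi)))
            if n_clip:
                logger.warning(
                    "bias_correct: clipped %d values of %s to [%g, %g] in %s",
                    n_clip, name, lo, hi, fut.scenario_id,
                )
            adj = np.clip(adj, lo, hi)
        corrected[name] = adj
    return ClimateIndexSeries(fut.scenario_id, fut.years, corrected)


def make_persistence(
    hind: ClimateIndexSeries,
    cfg: BiasCorrectionConfig | None = None,
    projection_years: np.ndarray | None = None,
) -> ClimateIndexSeries:
    """Climate-frozen counterfactual: every index held at its reference-period
    hindcast mean over the projection years."""
    cfg = cfg or BiasCorrectionConfig()
    if projection_years is None or len(projection_years) == 0:
        raise ForcingError("projection_years must be a non-empty range")
    projection_years = np.asarray(projection_years, dtype=int)
    ref = cfg.ref_years
    if not hind.contains_years(ref):
        raise ForcingError("hindcast does not cover the reference years")
    mask = np.isin(hind.years, ref)
    const = {
        name: np.full(projection_years.size, float(np.mean(vec[mask])))
        for name, vec in hind.indices.items()
    }
    return ClimateIndexSeries("persistence", projection_years, const)
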