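"""Catch-function layer: regressions linking ABC -> TAC -> realized catch.

Quota setting and fleet behaviour are emulated with stage-wise log-linear
regressions fit to a 1992-2017-style history,

    ln TAC_i = a_i + b_i ln ABC_i + sum_j g_ij ABC_j + sum_k t_ik I_k + e_i
    ln C_i   = a_i + b_i ln TAC_i + sum_j g_ij TAC_j + sum_k t_ik I_k + e_i,

where the cross terms carry other species' quotas in levels and I_k are 0/1
policy indicators.  Three ensemble members share these mean equations and
differ only in their assumed cross-equation residual grouping (independent /
two-group / three-group), mirroring a seemingly-unrelated-regression system
estimated equation-wise; predictions use the ensemble-mean mean relationship
(no lognormal retransformation term by default).  Hard management
constraints are applied on top: TAC <= ABC per species, and when the summed
TAC (plus any exogenous block for the rest of the complex) would exceed the
ecosystem cap, every modeled TAC is scaled down by one common factor so the
total hits the cap exactly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESIDUAL_GROUPINGS = ("independent", "two_group", "three_group")


class CapInfeasibleError(ValueError):
    """The exogenous TAC block alone meets or exceeds the cap."""


@dataclass
class QuotaRecord:
    """One historical year of quotas: ABC, TAC and catch per species plus
    policy indicator values."""

    year: int
    abc: dict[str, float]
    tac: dict[str, float]
    catch: dict[str, float]
    indicators: dict[str, float] = field(default_factory=dict)


@dataclass
class StageFit:
    """Fitted coefficients for one species at one stage (TAC or catch)."""

    intercept: float
    own_coef: float
    cross_coefs: dict[str, float]
    indicator_coefs: dict[str, float]
    resid_sd: float
    residuals: np.ndarray


@dataclass
class CatchFunctionModel:
    species: tuple[str, ...]
    indicator_names: tuple[str, ...]
    tac_stage: dict[str, StageFit]
    catch_stage: dict[str, StageFit]
    resid_corr: dict[str, dict[str, np.ndarray]]  # grouping -> stage -> corr matrix
    ensemble_weights: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 / 3.0 for g in RESIDUAL_GROUPINGS}
    )
    groupings: dict[str, list[list[str]]] | None = None
    retransform_bias: bool = False

    def __post_init__(self) -> None:
        w = np.array(list(self.ensemble_weights.values()))
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("ensemble weights must be non-negative and sum to 1")


def _default_groupings(species: tuple[str, ...]) -> dict[str, list[list[str]]]:
    """Illustrative residual groupings: fully independent; the two gadid-like
    species linked; all three linked."""
    sp = list(species)
    return {
        "independent": [[s] for s in sp],
        "two_group": [sp[:2], sp[2:]] if len(sp) > 2 else [sp],
        "three_group": [sp],
    }


def _fit_stage(
    history: list[QuotaRecord],
    species: tuple[str, ...],
    indicator_names: tuple[str, ...],
    x_field: str,
    y_field: str,
) -> dict[str, StageFit]:
    fits = {}
    for sp in species:
        rows_x, rows_y, used = [], [], []
        for rec in history:
            xv = getattr(rec, x_field)
            yv = getattr(rec, y_field)
            if xv[sp] <= 0 or yv[sp] <= 0 or any(xv[o] <= 0 for o in species):
                logger.warning("fit_catch_functions: dropping year %d for %s (non-positive value)", rec.year, sp)
                continue
            others = [o for o in species if o != sp]
            rows_x.append(
                [1.0, np.log(xv[sp])]
                + [xv[o] for o in others]
                + [rec.indicators.get(k, 0.0) for k in indicator_names]
            )
            rows_y.append(np.log(yv[sp]))
            used.append(rec.year)
        X = np.asarray(rows_x)
        y = np.asarray(rows_y)
        names = ["intercept", "own"] + [o for o in species if o != sp] + list(indicator_names)
        # drop degenerate (constant) columns other than the intercept
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.ptp(X[:, j]) > 1e-12:
                keep.append(j)
            else:
                logger.warning("fit_catch_functions: dropping constant column %r for %s", names[j], sp)
        Xk = X[:, keep]
        if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design for {sp} ({y_field} stage)")
        coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        resid = y - Xk @ coef
        dof = max(len(y) - Xk.shape[1], 1)
        full = np.zeros(X.shape[1])
        full[keep] = coef
        others = [o for o in species if o != sp]
        fits[sp] = StageFit(
            intercept=float(full[0]),
            own_coef=float(full[1]),
            cross_coefs={o: float(full[2 + i]) for i, o in enumerate(others)},
            indicator_coefs={
                k: float(full[2 + len(others) + i]) for i, k in enumerate(indicator_names)
            },
            resid_sd=float(np.sqrt(resid @ resid / dof)),
            residuals=resid,
        )
    return fits


def fit_catch_functions(
    history: list[QuotaRecord],
    species: tuple[str, ...] | None = None,
    indicator_names: tuple[str, ...] | None = None,
    groupings: dict[str, list[list[str]]] | None = None,
) -> CatchFunctionModel:
    """Fit both regression stages and the three-member residual ensemble.

    Point estimates are equation-wise least squares (the members share them);
    the members differ in the cross-equation residual correlations estimated
    under each grouping.  Needs >= 12 complete years.
    """
    if len(history) < 12:
        raise ValueError("need at least 12 years of quota history")
    if species is None:
        species = tuple(sorted(history[0].abc))
    if indicator_names is None:
        indicator_names = tuple(sorted(history[0].indicators))
    groupings = groupings or _default_groupings(species)

    tac_stage = _fit_stage(history, species, indicator_names, "abc", "tac")
    catch_stage = _fit_stage(history, species, indicator_names, "tac", "catch")

    resid_corr: dict[str, dict[str, np.ndarray]] = {}
    for gname, groups in groupings.items():
        resid_corr[gname] = {}
        for stage_name, stage in (("tac", tac_stage), ("catch", catch_stage)):
            k = len(species)
            corr = np.eye(k)
            resmat = np.column_stack([stage[sp].residuals for sp in species])
            sample = np.corrcoef(resmat, rowvar=False)
            for group in groups:
                for a, b in itertools.combinations(group, 2):
                    ia, ib = species.index(a), species.index(b)
                    corr[ia, ib] = corr[ib, ia] = sample[ia, ib]
            resid_corr[gname][stage_name] = corr

    return CatchFunctionModel(
        species=species,
        indicator_names=indicator_names,
        tac_stage=tac_stage,
        catch_stage=catch_stage,
        resid_corr=resid_corr,
        groupings=groupings,
    )


def _predict_stage(
    stage: dict[str, StageFit],
    species: tuple[str, ...],
    x: dict[str, float],
    indicators: dict[str, float],
    retransform_bias: bool,
) -> dict[str, float]:
    out = {}
    for sp in species:
        if x[sp] <= 0:
            raise ValueError(f"non-positive input for {sp}")
        f = stage[sp]
        lin = f.intercept + f.own_coef * np.log(x[sp])
        lin += sum(c * x[o] for o, c in f.cross_coefs.items())
        for k, c in f.indicator_coefs.items():
            if c != 0.0 and k not in indicators:
                raise KeyError(f"missing policy indicator {k!r}")
            lin += c * indicators.get(k, 0.0)
        if retransform_bias:
            lin += 0.5 * f.resid_sd**2
        out[sp] = float(np.exp(lin))
    return out


def predict_tac(
    m: CatchFunctionModel,
    abc: dict[str, float],
    indicators: dict[str, float] | None = None,
) -> dict[str, float]:
    """Deterministic mean-relationship TAC prediction, clipped at ABC.

    The caller applies :func:`apply_cap` afterwards (the cap needs the
    exogenous block, which is not this regression's business).
    """
    pred = _predict_stage(
        m.tac_stage, m.species, abc, indicators or {}, m.retransform_bias
    )
    out = {}
    for sp, v in pred.items():
        if v > abc[sp]:
            logger.warning("predict_tac: %s prediction %.0f t exceeds ABC %.0f t; clipped", sp, v, abc[sp])
            v = abc[sp]
        out[sp] = v
    return out


def apply_cap(
    tac: dict[str, float],
    exogenous_other_tac: float = 0.0,
    cap: float = 2_000_000.0,
) -> dict[str, float]:
    """Proportional-reduction ecosystem cap on summed TAC.

    If modeled TACs plus the exogenous block exceed the cap, every modeled
    TAC is scaled by the single factor that makes the total exactly equal the
    cap, preserving relative proportions.  Idempotent.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if any(v < 0 for v in tac.values()):
        raise ValueError("TACs must be non-negative")
    if exogenous_other_tac >= cap:
        raise CapInfeasibleError(
            f"exogenous TAC block ({exogenous_other_tac:.0f} t) meets or exceeds the cap"
        )
    total = sum(tac.values()) + exogenous_other_tac
    if total <= cap:
        return dict(tac)
    scale = (cap - exogenous_other_tac) / sum(tac.values())
    return {sp: v * scale for sp, v in tac.items()}


def predict_catch(
    m: CatchFunctionModel,
    tac: dict[str, float],
    indicators: dict[str, float] | None = None,
) -> dict[str, float]:
    """Deterministic mean-relationship catch prediction, clipped at TAC."""
    pred = _predict_stage(
        m.catch_stage, m.species, tac, indicators or {}, m.retransform_bias
    )
    out = {}
    for sp, v in pred.items():
        if v > tac[sp]:
            logger.warning("predict_catch: %s prediction %.0f t exceeds TAC %.0f t; clipped", sp, v, tac[sp])
            v = tac[sp]
        out[sp] = v
    return out


def loo_cv(
    history: list[QuotaRecord],
    species: tuple[str, ...] | None = None,
    indicator_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of the catch predictions.

    For each held-out year the stages are refit on the remaining years and
    catch is predicted from that year's actual TAC.  Accumulates, per species
    and per model ("ensemble" and the naive "catch_eq_abc" baseline): sum of
    differences, sum of percent differences, sum of squared differences, and
    sum of squared percent differences.
    """
    if len(history) < 5:
        raise ValueError("need at least 5 years for LOO-CV")
    if species is None:
        species = tuple(sorted(history[0].abc))
    acc: dict[tuple[str, str], dict[str, float]] = {}

    def add(model: str, sp: str, pred: float, obs: float) -> None:
        d = pred - obs
        p = d / obs
        cell = acc.setdefault(
            (model, sp),
            {"sum_diff": 0.0, "sum_pct_diff": 0.0, "sum_sq_diff": 0.0, "sum_sq_pct_diff": 0.0},
        )
        cell["sum_diff"] += d
        cell["sum_pct_diff"] += p
        cell["sum_sq_diff"] += d * d
        cell["sum_sq_pct_diff"] += p * p

    for i, held in enumerate(history):
        rest = history[:i] + history[i + 1 :]
        try:
            m = fit_catch_functions(rest, species=species, indicator_names=indicator_names)
            pred = predict_catch(m, held.tac, held.indicators)
        except (np.linalg.LinAlgError, ValueError) as e:
            logger.warning("loo_cv: skipping fold year %d (%s)", held.year, e)
            continue
        for sp in species:
            add("ensemble", sp, pred[sp], held.catch[sp])
            add("catch_eq_abc", sp, held.abc[sp], held.catch[sp])

    rows = [
        {"model": model, "species": sp, **metrics} for (model, sp), metrics in acc.items()
    ]
    return pd.DataFrame(rows).sort_values(["model", "species"]).reset_index(drop=True)


def history_to_frame(history: list[QuotaRecord]) -> pd.DataFrame:
    rows = []
    for rec in history:
        for sp in rec.abc:
            rows.append(
                {
                    "year": rec.year,
                    "species": sp,
                    "abc": rec.abc[sp],
                    "tac": rec.tac[sp],
                    "catch": rec.catch[sp],
                    **{f"ind_{k}": v for k, v in rec.indicators.items()},
                }
            )
    return pd.DataFrame(rows)
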