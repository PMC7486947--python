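"""Risk metrics relative to the persistence baseline.

The central quantity is the paired relative change

    dC_y = (value_y(scenario) - value_y(persistence)) / value_y(persistence)

computed replicate-by-replicate.  Risk is the fraction of replicates whose
period-mean dC falls below a threshold: decline (>10% drop), severe decline
(>50%), collapse (>80%), strict inequalities.  A warm stanza is a run of at
least ``run_length`` consecutive years with bottom temperature strictly above
a threshold (defaults 2.1 degC and 5 years).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"decline": 0.10, "severe_decline": 0.50, "collapse": 0.80}
WARM_STANZA_TEMP = 2.1
WARM_STANZA_RUN = 5


def delta_vs_persistence(series: np.ndarray, persistence: np.ndarray) -> np.ndarray:
    """Elementwise relative change vs the paired persistence series.

    Years where the persistence value is not positive are masked to NaN (and
    logged); equal series give exactly 0; a zero scenario value gives -1.
    """
    series = np.asarray(series, dtype=float)
    persistence = np.asarray(persistence, dtype=float)
    if series.shape != persistence.shape:
        raise ValueError("series must be year-aligned and equal length")
    bad = persistence <= 0
    if np.any(bad):
        logger.warning("delta_vs_persistence: masking %d years with non-positive baseline", int(bad.sum()))
    out = np.full(series.shape, np.nan)
    np.divide(series - persistence, persistence, out=out, where=~bad)
    return out


def default_periods(start: int = 2018, end: int = 2100, n: int = 4) -> list[tuple[int, int]]:
    """``n`` near-equal consecutive year windows spanning [start, end]."""
    edges = np.linspace(start, end + 1, n + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(n)]


def risk_probability(
    results: pd.DataFrame,
    metric: str = "catch",
    thresholds: dict[str, float] | None = None,
    periods: list[tuple[int, int]] | None = None,
    any_year: bool = False,
) -> pd.DataFrame:
    """Risk table over species x variant x scenario x period x threshold.

    ``results`` is the long ensemble table from :mod:`beringmse.mse` and must
    include the paired persistence runs.  For each cell the probability is
    the fraction of replicates whose period-mean dC (or, with ``any_year``,
    whose worst single year) is below -threshold, strictly.
    """
    thresholds = thresholds or dict(DEFAULT_THRESHOLDS)
    if periods is None:
        periods = default_periods(int(results.year.min()), int(results.year.max()))
    for lo, hi in periods:
        if hi < lo:
            raise ValueError(f"empty period ({lo}, {hi})")

    key = ["variant", "replicate", "species", "year"]
    pers = results[results.scenario == "persistence"].set_index(key)[metric]
    rows = []
    for (scen, var), sub in results[results.scenario != "persistence"].groupby(
        ["scenario", "variant"]
    ):
        sub = sub.copy()
        base = pers.reindex(
            pd.MultiIndex.from_frame(sub[key])
        ).to_numpy()
        if np.any(np.isnan(base)):
            raise ValueError(f"missing paired persistence rows for {scen}/{var}")
        sub["delta"] = delta_vs_persistence(sub[metric].to_numpy(), base)
        for lo, hi in periods:
            win = sub[(sub.year >= lo) & (sub.year <= hi)]
            for sp, g in win.groupby("species"):
                stat = g.groupby("replicate")["delta"].agg("min" if any_year else "mean")
                for name, thr in thresholds.items():
                    rows.append(
                        {
                            "species": sp,
                            "variant": var,
                            "scenario": scen,
                            "period_start": lo,
                            "period_end": hi,
                            "threshold": name,
                            "threshold_value": thr,
                            "probability": float(np.mean(stat < -thr)),
                            "n_replicates": int(stat.size),
                        }
                    )
    return pd.DataFrame(rows)


def detect_warm_stanzas(
    years: np.ndarray,
    temps: np.ndarray,
    threshold: float = WARM_STANZA_TEMP,
    run_length: int = WARM_STANZA_RUN,
) -> list[tuple[int, int]]:
    """Maximal runs of >= run_length consecutive years strictly above the
    temperature threshold, as (start_year, end_year) pairs, sorted."""
    years = np.asarray(years, dtype=int)
    temps = np.asarray(temps, dtype=float)
    if years.size == 0:
        raise ValueError("series must be non-empty")
    above = temps > threshold
    out = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            if j - i + 1 >= run_length:
                out.append((int(years[i]), int(years[j])))
            i = j + 1
        else:
            i += 1
    return out
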