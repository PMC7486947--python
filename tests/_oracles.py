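"""Independent brute-force oracles, deliberately written in plain loops with
no reuse of the package's vectorized implementations."""

from __future__ import annotations

import math


def advance_year_oracle(n, w_prev, z, maturity, recruits):
    """Spreadsheet-style one-year cohort update for a single species.

    ``n`` and ``z`` are lists for the outgoing year; returns next year's
    numbers-at-age with plus-group accumulation and ``recruits`` entering the
    first age class.
    """
    A = len(n)
    surv = [n[a] * math.exp(-z[a]) for a in range(A)]
    nxt = [0.0] * A
    nxt[0] = recruits
    for a in range(1, A):
        nxt[a] = surv[a - 1]
    nxt[A - 1] += surv[A - 1]
    return nxt


def ssb_oracle(n, w, maturity):
    return sum(m * x * ww for m, x, ww in zip(maturity, n, w))


def baranov_oracle(n, w, s, f, z):
    total = 0.0
    for a in range(len(n)):
        if s[a] * f == 0:
            continue
        total += (s[a] * f / z[a]) * (1 - math.exp(-z[a])) * n[a] * w[a]
    return total


def risk_count_oracle(period_mean_deltas, threshold):
    """Fraction of replicates whose period-mean relative change is strictly
    below -threshold."""
    hits = sum(1 for d in period_mean_deltas if d < -threshold)
    return hits / len(period_mean_deltas)


def warm_runs_oracle(years, temps, threshold, run_length):
    """Exhaustive scan for maximal runs of consecutive years strictly above
    the temperature threshold."""
    runs = []
    start = None
    for i, t in enumerate(temps):
        if t > threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= run_length:
                runs.append((years[start], years[i - 1]))
            start = None
    if start is not None and len(temps) - start >= run_length:
        runs.append((years[start], years[-1]))
    return runs
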