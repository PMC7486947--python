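"""Pressure-response threshold analysis: where does the catch response to
bottom temperature bend?

Pooled (temperature, relative-catch-change) points are smoothed with a
low-rank penalized regression spline (cubic B-spline basis of dimension k,
default 4, with an exact integrated-squared-curvature penalty whose strength
is chosen by generalized cross-validation).  First and second derivatives of
the smooth s(x) are taken by finite differences on a dense grid, and their
pointwise 95% confidence bands come from a residual bootstrap (default 1000
refits).  The second-derivative band is additionally smoothed with a loess
of span 10% before use.  The tipping point is the temperature where s''(x)
changes sign and the smoothed s'' confidence interval is most different from
zero in the flanking region; if no sign change has a flanking interval
excluding zero, no tipping point is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

GRID_SIZE = 200
DEFAULT_K = 4
DEFAULT_N_BOOT = 1000
LOESS_SPAN = 0.10


def _knot_vector(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector giving ``k`` basis functions; interior knots at
    quantiles of the data."""
    n_interior = k - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design(x: np.ndarray, t: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.clip(x, t[0], t[-1])
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def _curvature_penalty(t: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Gram matrix of basis second derivatives, integrated exactly.

    Second derivatives of cubic B-splines are piecewise linear, so two-point
    Gauss-Legendre per knot span is exact; the null space of the resulting
    penalty is exactly the linear functions.
    """
    P = np.zeros((k, k))
    spans = np.unique(t)
    gauss = np.array([-1, 1]) / np.sqrt(3)
    d2 = [BSpline(t, np.eye(k)[i], degree).derivative(2) for i in range(k)]
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2, (b - a) / 2
        for xg in mid + half * gauss:
            v = np.array([f(xg) for f in d2])
            P += half * np.outer(v, v)
    return P


@dataclass
class ThresholdFit:
    """Penalized-spline fit of the pooled pressure-response points, plus
    (after :func:`bootstrap_derivatives`) derivative confidence bands."""

    x: np.ndarray
    y: np.ndarray
    k: int
    knots: np.ndarray
    coefs: np.ndarray
    alpha: float
    grid: np.ndarray
    s: np.ndarray
    residuals: np.ndarray
    edf: float
    n_boot: int = 0
    loess_span: float = LOESS_SPAN
    bands: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def d1(self) -> np.ndarray:
        return np.gradient(self.s, self.grid, edge_order=2)

    @property
    def d2(self) -> np.ndarray:
        return np.gradient(self.d1, self.grid, edge_order=2)


def _gcv_alpha(X: np.ndarray, y: np.ndarray, P: np.ndarray) -> float:
    """Generalized cross-validation over a log-spaced penalty grid."""
    XtX = X.T @ X
    Xty = X.T @ y
    n = y.size
    best, best_alpha = np.inf, 1.0
    for alpha in np.logspace(-6, 8, 57):
        A = XtX + alpha * P
        try:
            c = np.linalg.solve(A, Xty)
            edf = float(np.trace(np.linalg.solve(A, XtX)))
        except np.linalg.LinAlgError:
            continue
        rss = float(np.sum((y - X @ c) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best:
            best, best_alpha = gcv, alpha
    return best_alpha


def fit_threshold(
    T: np.ndarray, dC: np.ndarray, k: int = DEFAULT_K, grid_size: int = GRID_SIZE
) -> ThresholdFit:
    """Fit s(x) to the pooled (temperature, relative change) points.

    The basis dimension ``k`` (default 4) caps the smooth's flexibility, as
    in threshold analyses that deliberately under-parameterize to avoid
    overfitting; the curvature penalty weight is chosen by GCV.
    """
    T = np.asarray(T, dtype=float)
    dC = np.asarray(dC, dtype=float)
    ok = np.isfinite(T) & np.isfinite(dC)
    T, dC = T[ok], dC[ok]
    if T.size < 20:
        raise ValueError("need at least 20 points")
    if k < 3:
        raise ValueError("basis dimension must be >= 3")
    if np.ptp(T) <= 0:
        raise ValueError("pressure variable has no spread")

    t = _knot_vector(T, k)
    X = _design(T, t)
    P = _curvature_penalty(t, k)
    alpha = _gcv_alpha(X, dC, P)
    A = X.T @ X + alpha * P
    coefs = np.linalg.solve(A, X.T @ dC)
    fitted = X @ coefs
    edf = float(np.trace(np.linalg.solve(A, X.T @ X)))

    grid = np.linspace(T.min(), T.max(), grid_size)
    G = _design(grid, t)
    return ThresholdFit(
        x=T, y=dC, k=k, knots=t, coefs=coefs, alpha=alpha,
        grid=grid, s=G @ coefs, residuals=dC - fitted, edf=edf,
    )


def bootstrap_derivatives(
    fit: ThresholdFit, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> ThresholdFit:
    """Residual-bootstrap 95% bands for s, s' and s'' on the grid.

    Each replicate refits (at the original penalty weight) to
    y* = fitted + resampled residuals; derivatives are central finite
    differences on the grid; bands are pointwise 2.5/97.5 percentiles.  The
    s'' bounds are additionally loess-smoothed (span 10%) into
    ``bands["d2_lo_smooth"]`` / ``bands["d2_hi_smooth"]`` for tipping-point
    detection.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    X = _design(fit.x, fit.knots)
    G = _design(fit.grid, fit.knots)
    P = _curvature_penalty(fit.knots, fit.k)
    A = cho_factor(X.T @ X + fit.alpha * P)
    fitted = X @ fit.coefs

    s_b = np.empty((n_boot, fit.grid.size))
    d1_b = np.empty_like(s_b)
    d2_b = np.empty_like(s_b)
    n_fail = 0
    for b in range(n_boot):
        y_star = fitted + rng.choice(fit.residuals, size=fit.residuals.size, replace=True)
        try:
            c = cho_solve(A, X.T @ y_star)
        except np.linalg.LinAlgError:
            n_fail += 1
            s_b[b] = d1_b[b] = d2_b[b] = np.nan
            continue
        s = G @ c
        d1 = np.gradient(s, fit.grid, edge_order=2)
        s_b[b], d1_b[b], d2_b[b] = s, d1, np.gradient(d1, fit.grid, edge_order=2)
    if n_fail:
        logger.warning("bootstrap_derivatives: %d/%d replicates failed", n_fail, n_boot)
        if n_fail > 0.1 * n_boot:
            raise RuntimeError(f"too many bootstrap failures ({n_fail}/{n_boot})")

    bands = {}
    for name, arr in (("s", s_b), ("d1", d1_b), ("d2", d2_b)):
        bands[f"{name}_lo"] = np.nanpercentile(arr, 2.5, axis=0)
        bands[f"{name}_hi"] = np.nanpercentile(arr, 97.5, axis=0)
    for side in ("lo", "hi"):
        bands[f"d2_{side}_smooth"] = lowess(
            bands[f"d2_{side}"], fit.grid, frac=fit.loess_span, return_sorted=False
        )
    fit.bands = bands
    fit.n_boot = n_boot
    return fit


@dataclass
class TippingPoint:
    """Detected tipping temperature (or None) with supporting diagnostics."""

    temperature: float | None
    score: float
    candidates: list[dict]
    d1_significant_regions: list[tuple[float, float]]


def _excluding_zero(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return (lo > 0) | (hi < 0)


def _regions(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    out = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            out.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return out


def find_tipping_point(fit: ThresholdFit, flank_frac: float = 0.10) -> TippingPoint:
    """Locate the tipping temperature from a band-filled fit.

    Candidates are grid locations where the second derivative of the point
    estimate changes sign.  A candidate qualifies if, within a flanking
    window of ``flank_frac`` of the temperature range on either side, the
    loess-smoothed s'' confidence interval excludes zero somewhere; its score
    is the largest distance of that interval from zero (min of |bounds|)
    over the window.  The best-scoring candidate wins; ties break toward the
    larger peak |s''| in the window.  Absence is a valid result.
    """
    if "d2_lo_smooth" not in fit.bands:
        raise ValueError("run bootstrap_derivatives first")
    grid = fit.grid
    d2 = fit.d2
    lo, hi = fit.bands["d2_lo_smooth"], fit.bands["d2_hi_smooth"]
    excl = _excluding_zero(lo, hi)
    half_window = max(int(round(flank_frac * grid.size)), 1)

    candidates = []
    for i in range(d2.size - 1):
        if d2[i] == 0.0 or d2[i] * d2[i + 1] >= 0:
            continue
        # linear interpolation of the crossing temperature
        x_c = grid[i] + (grid[i + 1] - grid[i]) * d2[i] / (d2[i] - d2[i + 1])
        sl = slice(max(i - half_window, 0), min(i + 1 + half_window, grid.size))
        win_excl = excl[sl]
        if not np.any(win_excl):
            continue
        dist = np.minimum(np.abs(lo[sl]), np.abs(hi[sl]))
        score = float(np.max(dist[win_excl]))
        candidates.append(
            {
                "temperature": float(x_c),
                "score": score,
                "peak_abs_d2": float(np.max(np.abs(d2[sl]))),
            }
        )

    d1_regions = _regions(grid, _excluding_zero(fit.bands["d1_lo"], fit.bands["d1_hi"]))
    if not candidates:
        return TippingPoint(None, 0.0, [], d1_regions)
    best = max(candidates, key=lambda c: (c["score"], c["peak_abs_d2"]))
    return TippingPoint(best["temperature"], best["score"], candidates, d1_regions)


def threshold_analysis(
    T: np.ndarray,
    dC: np.ndarray,
    k: int = DEFAULT_K,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[ThresholdFit, TippingPoint]:
    """Convenience wrapper: fit, bootstrap bands, locate the tipping point."""
    fit = bootstrap_derivatives(fit_threshold(T, dC, k=k), n_boot=n_boot, seed=seed)
    return fit, find_tipping_point(fit)
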