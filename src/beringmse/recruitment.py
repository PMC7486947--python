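"""Climate-enhanced Ricker recruitment-per-spawner model.

The model (often labelled "logistic" in the regional literature, but
Ricker-form as written) is, on the log scale,

    ln R_y = alpha - beta0 * B_{y-1} + ln B_{y-1} + sum_j beta_j X_{j,y} + eps_y,
    eps_y ~ N(0, sigma^2),

so recruits-per-spawner ln(R/B) is linear in (-B, X) and the fit is ordinary
least squares, equivalent to Gaussian maximum likelihood.  The coefficient
sampling covariance from the fit feeds the parameter-replicate draws used to
propagate estimation uncertainty through projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_COVARIATES = ("zoop_spring", "zoop_fall", "bottom_temp", "cold_pool")


class SingularDesignError(ValueError):
    """The recruitment design matrix is rank deficient."""


@dataclass
class RecruitObservation:
    year: int
    spawning_biomass: float  # tons, spawning stock in the prior year
    recruitment: float  # age-1 recruits (model number units)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spawning_biomass <= 0 or self.recruitment <= 0:
            raise ValueError("spawning biomass and recruitment must be positive")


@dataclass
class RecruitmentModel:
    """Fitted (or true) parameters of the climate-enhanced Ricker model.

    ``cov`` is the joint sampling covariance of (alpha, beta0, betas...) in
    the order (alpha, beta0, *covariate_names).
    """

    alpha: float
    beta0: float
    betas: dict[str, float]
    sigma: float
    covariate_names: tuple[str, ...]
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not set(self.betas) <= set(self.covariate_names):
            raise ValueError("betas keys must be a subset of covariate_names")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            k = 2 + len(self.covariate_names)
            if self.cov.shape != (k, k):
                raise ValueError(f"cov must be {k}x{k}")
            if not np.allclose(self.cov, self.cov.T, atol=1e-10):
                raise ValueError("cov must be symmetric")

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta0] + [self.betas.get(c, 0.0) for c in self.covariate_names]
        )

    def with_coefs(self, vec: np.ndarray) -> "RecruitmentModel":
        betas = dict(zip(self.covariate_names, vec[2:]))
        return RecruitmentModel(
            alpha=float(vec[0]),
            beta0=float(vec[1]),
            betas=betas,
            sigma=self.sigma,
            covariate_names=self.covariate_names,
            cov=self.cov,
        )


def fit_recruitment(
    obs: list[RecruitObservation],
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
) -> RecruitmentModel:
    """Least-squares fit of the log recruits-per-spawner regression.

    Requires at least (number of coefficients + 2) observations.  Residual SD
    uses the degrees-of-freedom-corrected estimator sqrt(SSR / (n - k)).
    Raises :class:`SingularDesignError` naming the offending columns when the
    design is rank deficient (e.g. duplicated covariates).
    """
    covariate_names = tuple(covariate_names)
    k = 2 + len(covariate_names)
    if len(obs) < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} coefficients")

    B = np.array([o.spawning_biomass for o in obs])
    R = np.array([o.recruitment for o in obs])
    X = np.column_stack(
        [np.ones(len(obs)), -B]
        + [np.array([o.covariates[c] for o in obs]) for c in covariate_names]
    )
    y = np.log(R) - np.log(B)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by checking each against the span of the others
        names = ["intercept", "spawning_biomass"] + list(covariate_names)
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(names[j])
        raise SingularDesignError(f"collinear design columns: {bad or names}")

    coef, ssr_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    dof = len(obs) - k
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    # design used -B, so the slope on that column is +beta0 directly
    return RecruitmentModel(
        alpha=float(coef[0]),
        beta0=float(coef[1]),
        betas=dict(zip(covariate_names, coef[2:])),
        sigma=float(np.sqrt(sigma2)),
        covariate_names=covariate_names,
        cov=cov,
    )


def predict_recruitment(
    m: RecruitmentModel,
    spawning_biomass: float,
    covariates: dict[str, float],
    eps: float = 0.0,
) -> float:
    """Recruitment R = exp(alpha - beta0*B + ln B + sum beta_j X_j + eps)."""
    if spawning_biomass <= 0:
        raise ValueError("spawning biomass must be positive")
    lin = m.alpha - m.beta0 * spawning_biomass + np.log(spawning_biomass) + eps
    for name in m.covariate_names:
        beta = m.betas.get(name, 0.0)
        if beta != 0.0 and name not in covariates:
            raise KeyError(f"missing covariate {name!r}")
        lin += beta * covariates.get(name, 0.0)
    return float(np.exp(lin))


def draw_parameter_replicates(
    m: RecruitmentModel,
    n: int,
    seed: int | np.random.Generator,
    joint: bool = True,
    positive: tuple[str, ...] = (),
) -> list[RecruitmentModel]:
    """Draw ``n`` coefficient vectors from the estimation-uncertainty distribution.

    Default is the joint multivariate normal N(point estimate, cov); with
    ``joint=False`` each coefficient is drawn from its marginal normal
    independently.  Coefficients named in ``positive`` (e.g. ``"beta0"``,
    whose sign a Ricker model needs for self-limitation) are instead drawn
    from the moment-matched lognormal through a Gaussian copula, preserving
    the joint correlation structure while enforcing positivity.  Seeded and
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.cov is None:
        raise ValueError("model has no sampling covariance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = m.coef_vector
    sd = np.sqrt(np.diag(m.cov))
    if joint:
        try:
            np.linalg.cholesky(m.cov + 1e-12 * np.eye(len(mean)))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError("covariance is not positive semi-definite") from e
        draws = rng.multivariate_normal(mean, m.cov, size=n, method="svd")
    else:
        draws = mean + rng.normal(size=(n, mean.size)) * sd
    if positive:
        names = ["alpha", "beta0"] + list(m.covariate_names)
        for pname in positive:
            j = names.index(pname)
            mu, s = mean[j], sd[j]
            if mu <= 0 or s == 0:
                continue  # lognormal undefined for non-positive location
            s_ln2 = np.log1p((s / mu) ** 2)
            mu_ln = np.log(mu) - 0.5 * s_ln2
            z = (draws[:, j] - mu) / s
            draws[:, j] = np.exp(mu_ln + np.sqrt(s_ln2) * z)
    return [m.with_coefs(d) for d in draws]


def observations_to_frame(obs: list[RecruitObservation]) -> pd.DataFrame:
    rows = [
        {"year": o.year, "ssb": o.spawning_biomass, "recruits": o.recruitment, **o.covariates}
        for o in obs
    ]
    return pd.DataFrame(rows)


def observations_from_frame(df: pd.DataFrame) -> list[RecruitObservation]:
    cov_cols = [c for c in df.columns if c not in ("year", "ssb", "recruits")]
    return [
        RecruitObservation(
            year=int(r["year"]),
            spawning_biomass=float(r["ssb"]),
            recruitment=float(r["recruits"]),
            covariates={c: float(r[c]) for c in cov_cols},
        )
        for _, r in df.iterrows()
    ]
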