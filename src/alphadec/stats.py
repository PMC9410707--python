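"""Standardization, outcome models, multiplicity correction, prior updating.

Numeric variables are scaled to mean 0 / sd 0.5 (so a binary dummy and a
continuous predictor move the outcome on comparable scales), outcomes are
regressed on age and covariates with either a deterministic OLS backend or
an MCMC backend with Cauchy priors, the number of effective tests among
correlated outcomes is computed from the eigenvalue spread of their
correlation matrix, and posterior coefficient distributions from one cohort
can be turned into parametric priors for an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

__all__ = [
    "ModelSpec",
    "ModelResult",
    "StatsError",
    "CollinearityError",
    "gelman_scale",
    "zscore",
    "effective_tests",
    "adjust_alpha",
    "fit_outcome_model",
    "correlation_table",
    "posterior_to_prior",
]


class StatsError(ValueError):
    pass


class CollinearityError(StatsError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: "
                         f"{self.columns}")


def gelman_scale(values) -> np.ndarray:
    """Scale to mean 0, sd 0.5: (x - mean) / (2 * sd), sample sd (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance input cannot be scaled")
    return (x - x.mean()) / (2.0 * sd)


def zscore(values) -> np.ndarray:
    """Plain standardization to mean 0, sd 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance input cannot be scaled")
    return (x - x.mean()) / sd


def effective_tests(corr: np.ndarray) -> float:
    """Effective number of independent tests among M correlated outcomes.

    Meff = 1 + (M - 1) * (1 - Var(lambda)/M), with lambda the eigenvalues of
    the outcome correlation matrix and Var the sample variance (ddof=1).
    Identity gives M; a perfectly correlated pair gives 1.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise StatsError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise StatsError("correlation matrix must be symmetric")
    m = c.shape[0]
    if m == 1:
        return 1.0
    lam = np.linalg.eigvalsh(c)
    return float(1.0 + (m - 1) * (1.0 - np.var(lam, ddof=1) / m))


def adjust_alpha(alpha: float = 0.05, meff: float = 1.0,
                 method: str = "sidak") -> tuple[float, float]:
    """Multiplicity-adjusted significance level and matching interval level.

    sidak: 1 - (1 - alpha)^(1/Meff);  bonferroni: alpha / Meff.
    Returns (adjusted_alpha, interval_level = 1 - adjusted_alpha).
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must lie in (0, 1)")
    if meff < 1:
        raise StatsError("Meff must be >= 1")
    if method == "sidak":
        adj = 1.0 - (1.0 - alpha) ** (1.0 / meff)
    elif method == "bonferroni":
        adj = alpha / meff
    else:
        raise StatsError(f"unknown method {method!r}")
    return float(adj), float(1.0 - adj)


@dataclass
class ModelSpec:
    """One outcome model: predictors, backend and interval level.

    Categorical predictors (object/categorical dtype) are treatment coded
    with the first level as reference.  ``prior`` is the (location, scale)
    of the Cauchy prior used by the MCMC backend; per-coefficient priors
    can be overridden through ``coef_priors`` (name -> ("normal", mu, sd)
    or ("cauchy", loc, scale)), which is how sequential prior updating
    feeds one cohort's posteriors into the next fit.
    """

    outcome: str
    predictors: list[str]
    backend: str = "ols"
    prior: tuple[float, float] = (0.0, 2.5)
    coef_priors: dict = field(default_factory=dict)
    interval_level: float = 0.95
    n_steps: int = 1500
    n_burn: int = 500
    n_walkers: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.interval_level < 1:
            raise StatsError("interval_level must lie in (0.5, 1)")


@dataclass
class ModelResult:
    """Standardized coefficients with interval bounds and significance flags."""

    table: pd.DataFrame  # index: predictor; columns: estimate, lower, upper, significant
    backend: str
    interval_level: float
    draws: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def coefficient(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])


def _design_matrix(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    missing = [c for c in [spec.outcome, *spec.predictors] if c not in data.columns]
    if missing:
        raise StatsError(f"missing columns: {missing}")
    sub = data[[spec.outcome, *spec.predictors]].dropna()
    y = sub[spec.outcome].astype(float)
    cols = {}
    for name in spec.predictors:
        col = sub[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol]
        else:
            cols[name] = col.astype(float)
    X = pd.DataFrame(cols, index=sub.index)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        arr = Xc.to_numpy()
        for j, name in enumerate(Xc.columns):
            if name == "const":
                continue
            reduced = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(name)
        raise CollinearityError(bad or list(X.columns))
    return Xc, y


def _fit_ols(spec: ModelSpec, X: pd.DataFrame, y: pd.Series) -> ModelResult:
    model = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    ci = model.conf_int(alpha=1.0 - spec.interval_level)
    tab = pd.DataFrame({
        "estimate": model.params,
        "lower": ci[:, 0],
        "upper": ci[:, 1],
    }, index=X.columns)
    tab["significant"] = (tab["lower"] > 0) | (tab["upper"] < 0)
    return ModelResult(tab, "ols", spec.interval_level,
                       diagnostics={"nobs": int(model.nobs),
                                    "r_squared": float(model.rsquared)})


def _log_prior(theta: np.ndarray, names: list[str], spec: ModelSpec) -> float:
    lp = 0.0
    for val, name in zip(theta[:-1], names):
        kind, a, b = spec.coef_priors.get(name, ("cauchy", *spec.prior))
        if kind == "cauchy":
            lp += sp_stats.cauchy.logpdf(val, loc=a, scale=b)
        elif kind == "normal":
            lp += sp_stats.norm.logpdf(val, loc=a, scale=b)
        else:
            raise StatsError(f"unknown prior family {kind!r}")
    log_sigma = theta[-1]
    if not -10 < log_sigma < 10:
        return -np.inf
    return lp


def _fit_bayes(spec: ModelSpec, X: pd.DataFrame, y: pd.Series) -> ModelResult:
    import emcee

    names = list(X.columns)
    Xa, ya = X.to_numpy(), y.to_numpy()
    ols = sm.OLS(ya, Xa).fit()

    def log_prob(theta):
        lp = _log_prior(theta, names, spec)
        if not np.isfinite(lp):
            return -np.inf
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        resid = ya - Xa @ beta
        ll = -0.5 * np.sum(resid ** 2) / sigma ** 2 - ya.size * log_sigma
        return lp + ll

    ndim = Xa.shape[1] + 1
    rng = np.random.default_rng(spec.seed)
    start = np.concatenate([ols.params, [np.log(np.sqrt(ols.scale))]])
    p0 = start + 1e-3 * rng.standard_normal((spec.n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        spec.n_walkers, ndim, log_prob,
        moves=emcee.moves.StretchMove(),
    )
    sampler.random_state = np.random.RandomState(spec.seed).get_state()
    sampler.run_mcmc(p0, spec.n_steps, progress=False)
    chain = sampler.get_chain(discard=spec.n_burn, flat=True)
    draws = pd.DataFrame(chain[:, :-1], columns=names)

    lo_q = 0.5 * (1.0 - spec.interval_level)
    tab = pd.DataFrame({
        "estimate": draws.mean(),
        "lower": draws.quantile(lo_q),
        "upper": draws.quantile(1.0 - lo_q),
    })
    tab["significant"] = (tab["lower"] > 0) | (tab["upper"] < 0)
    acc = float(np.mean(sampler.acceptance_fraction))
    return ModelResult(tab, "bayes", spec.interval_level, draws=draws,
                       diagnostics={"acceptance_fraction": acc,
                                    "nobs": int(ya.size),
                                    "converged": 0.1 < acc < 0.9})


def fit_outcome_model(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Fit one outcome model; numeric variables are expected pre-scaled.

    The OLS backend is deterministic and reports analytic intervals at
    ``interval_level``; the MCMC backend samples the posterior under the
    configured priors and reports equal-tailed credible intervals.  Both
    flag a predictor significant when its interval excludes zero.
    """
    X, y = _design_matrix(spec, data)
    if spec.backend == "ols":
        return _fit_ols(spec, X, y)
    if spec.backend == "bayes":
        return _fit_bayes(spec, X, y)
    raise StatsError(f"unknown backend {spec.backend!r}")


def correlation_table(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations on complete cases (listwise deletion)."""
    sub = table[columns] if columns is not None else table
    sub = sub.dropna()
    if len(sub) < 3:
        raise StatsError("need at least 3 complete cases")
    return sub.corr(method="pearson")


def posterior_to_prior(result: ModelResult, family: str = "normal") -> dict:
    """Approximate each posterior marginal by a parametric prior spec.

    Returns a ``coef_priors`` mapping suitable for a subsequent ModelSpec,
    implementing sequential updating across cohorts.  The default normal
    family matches mean and sd of the stored draws.
    """
    if result.draws is None:
        raise StatsError("result has no stored posterior draws")
    priors = {}
    for name in result.draws.columns:
        d = result.draws[name].to_numpy()
        if family == "normal":
            priors[name] = ("normal", float(d.mean()), float(d.std(ddof=1)))
        elif family == "cauchy":
            loc = float(np.median(d))
            scale = float(0.5 * (np.quantile(d, 0.75) - np.quantile(d, 0.25)))
            priors[name] = ("cauchy", loc, scale)
        else:
            raise StatsError(f"unknown prior family {family!r}")
    return priors
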