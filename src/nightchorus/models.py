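"""Standardised composites and count GLMs with family selection.

Site-level sonotype richness (a count) is modelled against one z-scored
acoustic index or composite index, with Reserve (study area) as a
two-level fixed factor, under a log link:

    log mu_i = b0 + b1 * z(index_i) + b2 * reserve_i

Five count families are fitted by direct maximum likelihood — Poisson,
negative binomial NB1 (variance mu(1+alpha)) and NB2 (variance
mu + mu^2/theta), generalized Poisson, and mean-parameterised
Conway-Maxwell-Poisson (CMP) — and compared by AIC, with ties
(delta AIC < 2) broken toward the Pearson dispersion (chi^2/df)
closest to 1. Reported per fit: two-sided Wald slope p-value, Efron's
pseudo-R^2 = 1 - sum((y - mu)^2) / sum((y - ybar)^2), AIC and the
small-sample AICc.

Composites are equal-weight sums of z-scored indices, re-standardised
to mean 0 / sd 1 so composites of different sizes share a scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "SINGLE_PREDICTORS",
    "COMPOSITE_PREDICTORS",
    "CompositeSpec",
    "GLMFit",
    "ModelSelectionResult",
    "zscore",
    "make_composite",
    "family_loglik",
    "fit_glm",
    "select_model",
    "fit_and_select",
    "run_model_grid",
    "poisson_r2_callback",
]

FAMILIES = ("poisson", "nb1", "nb2", "genpois", "cmp")

SINGLE_PREDICTORS = ("act", "aei", "hf", "sm")
COMPOSITE_PREDICTORS = (
    ("hf", "sm"),
    ("aei", "hf", "sm"),
    ("act", "hf", "sm"),
    ("act", "aei", "hf", "sm"),
)

_MAX_CMP_TERMS = 10_000


# ---------------------------------------------------------------------------
# Standardisation and composites


def zscore(values, name: str = "values") -> tuple[np.ndarray, float, float]:
    """z = (x - mean) / sd with the n-1 sd; returns (z, mean, sd)."""
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 2:
        raise ValueError(f"zscore of {name!r} needs length >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"{name!r} has zero variance; z-score undefined")
    return (x - mean) / sd, mean, sd


@dataclass(frozen=True)
class CompositeSpec:
    """Standardisation parameters of an equal-weight composite index."""

    components: tuple[str, ...]
    stage1_means: dict[str, float]
    stage1_sds: dict[str, float]
    stage2_mean: float
    stage2_sd: float


def make_composite(index_site_means: pd.DataFrame,
                   components) -> tuple[pd.Series, CompositeSpec]:
    """Equal-weight composite: z-score components, sum, re-z-score.

    ``index_site_means`` is indexed by site with one column per index.
    """
    components = tuple(components)
    if not components:
        raise ValueError("a composite needs at least one component")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    total = np.zeros(len(index_site_means))
    for comp in sorted(components):
        z, m, s = zscore(index_site_means[comp].to_numpy(), name=comp)
        means[comp], sds[comp] = m, s
        total = total + z
    z2, m2, s2 = zscore(total, name="composite(" + "+".join(components) + ")")
    spec = CompositeSpec(components=components, stage1_means=means,
                         stage1_sds=sds, stage2_mean=m2, stage2_sd=s2)
    return pd.Series(z2, index=index_site_means.index), spec


# ---------------------------------------------------------------------------
# Family log-likelihoods


def _poisson_ll(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1)


def _nb_theta_ll(y, mu, theta):
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu)))


def _genpois_ll(y, mu, xi):
    lam = mu * (1.0 - xi)
    inner = lam + xi * y
    if np.any(inner <= 0) or np.any(lam <= 0):
        return np.full_like(np.asarray(y, dtype=float), -np.inf)
    return (np.log(lam) + (y - 1) * np.log(inner) - inner - gammaln(y + 1))


def _cmp_log_terms(log_lam: np.ndarray, lgamma_grid: np.ndarray,
                   nu: float) -> np.ndarray:
    """(n, G) log of the unnormalised CMP pmf over the y grid."""
    y = np.arange(len(lgamma_grid))
    return np.outer(log_lam, y) - nu * lgamma_grid[None, :]


def _cmp_grid(mu: np.ndarray, nu: float, y_obs_max: float = 0.0) -> np.ndarray:
    """gammaln(y+1) over a y grid wide enough for the series tail."""
    mu_max = float(np.max(mu))
    sd_guess = np.sqrt(mu_max / min(nu, 1.0))
    y_max = int(min(_MAX_CMP_TERMS,
                    max(50, y_obs_max + 1, np.ceil(mu_max + 12 * sd_guess + 25))))
    return gammaln(np.arange(y_max + 1) + 1.0)


def _cmp_pmf_stats(log_lam: np.ndarray, lgamma_grid: np.ndarray, nu: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log_Z, mean, variance) of the CMP series at each log(lambda)."""
    y = np.arange(len(lgamma_grid), dtype=np.float64)
    terms = _cmp_log_terms(log_lam, lgamma_grid, nu)
    m = terms.max(axis=1, keepdims=True)
    p = np.exp(terms - m)
    z = p.sum(axis=1)
    p /= z[:, None]
    mean = p @ y
    var = p @ (y * y) - mean ** 2
    return np.log(z) + m[:, 0], mean, var


def _cmp_solve_log_lambda(mu: np.ndarray, nu: float,
                          lgamma_grid: np.ndarray) -> np.ndarray:
    """Per-observation log(lambda) giving CMP mean mu at dispersion nu.

    Damped Newton on log(lambda); the mean is increasing with
    d(mean)/d(log lambda) = variance, so steps are well-scaled.
    Starts from the Shmueli et al. moment approximation.
    """
    mu = np.asarray(mu, dtype=np.float64)
    approx = np.maximum(mu + (nu - 1.0) / (2.0 * nu), np.maximum(0.05 * mu, 1e-6))
    log_lam = nu * np.log(approx)
    for _ in range(40):
        _, mean, var = _cmp_pmf_stats(log_lam, lgamma_grid, nu)
        err = mu - mean
        if np.max(np.abs(err) / np.maximum(mu, 1e-12)) < 1e-11:
            break
        log_lam = log_lam + np.clip(err / np.maximum(var, 1e-12), -4.0, 4.0)
    return log_lam


def _cmp_ll(y, mu, nu):
    lgamma_grid = _cmp_grid(mu, nu, float(np.max(y)))
    log_lam = _cmp_solve_log_lambda(mu, nu, lgamma_grid)
    log_z, _, _ = _cmp_pmf_stats(log_lam, lgamma_grid, nu)
    return y * log_lam - nu * gammaln(np.asarray(y, dtype=float) + 1.0) - log_z


def family_loglik(family: str, y, mu, shape: float | None = None) -> float:
    """Exact summed log-likelihood of counts ``y`` at means ``mu``.

    ``shape`` is theta for NB2 (variance mu + mu^2/theta), alpha for
    NB1 (variance mu(1+alpha)), xi for generalized Poisson, nu for CMP
    (nu = 1 recovers Poisson); Poisson takes no shape.
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integers")
    if family == "poisson":
        ll = _poisson_ll(y, mu)
    elif family == "nb2":
        if shape is None or shape <= 0:
            raise ValueError("NB2 requires theta > 0")
        ll = _nb_theta_ll(y, mu, shape)
    elif family == "nb1":
        if shape is None or shape <= 0:
            raise ValueError("NB1 requires alpha > 0")
        ll = _nb_theta_ll(y, mu, mu / shape)
    elif family == "genpois":
        if shape is None or not (0.0 <= shape < 1.0):
            raise ValueError("generalized Poisson requires xi in [0, 1)")
        if shape == 0.0:
            ll = _poisson_ll(y, mu)
        else:
            ll = _genpois_ll(y, mu, shape)
    elif family == "cmp":
        if shape is None or shape <= 0:
            raise ValueError("CMP requires nu > 0")
        ll = _cmp_ll(y, mu, shape)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(np.sum(ll))


def _family_variance(family: str, mu: np.ndarray,
                     shape: float | None) -> np.ndarray:
    """Variance function used for the Pearson dispersion statistic."""
    if family == "poisson":
        return mu
    if family == "nb2":
        return mu + mu ** 2 / shape
    if family == "nb1":
        return mu * (1.0 + shape)
    if family == "genpois":
        return mu / (1.0 - shape) ** 2
    if family == "cmp":
        lgamma_grid = _cmp_grid(mu, shape)
        log_lam = _cmp_solve_log_lambda(mu, shape, lgamma_grid)
        _, _, var = _cmp_pmf_stats(log_lam, lgamma_grid, shape)
        return var
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GLMFit:
    """One fitted count GLM: log link, index slope, reserve effect."""

    family: str
    coefficients: dict[str, float]
    shape: float | None
    log_likelihood: float
    aic: float
    aicc: float
    pearson_dispersion: float
    slope_se: float
    slope_p_value: float
    efron_r2: float
    n: int
    k: int
    converged: bool
    fitted_mu: np.ndarray = field(repr=False, default=None)


def _shape_transform(family: str):
    """(to_shape, start_grid) for the unconstrained shape parameter."""
    if family in ("nb2", "nb1"):
        return lambda s: np.exp(np.clip(s, -7.0, 21.0)), (np.log(0.5), np.log(20.0))
    if family == "genpois":
        # xi in [0, 0.95) via a scaled sigmoid
        return lambda s: 0.95 * expit(s), (-4.0, 0.0)
    if family == "cmp":
        # nu in ~[0.08, 20]: wide enough for strong over/underdispersion
        return lambda s: np.exp(np.clip(s, -2.5, 3.0)), (np.log(0.5), 0.5)
    return None, ()


def _design(predictor: np.ndarray, reserve) -> tuple[np.ndarray, str]:
    levels = sorted(pd.unique(np.asarray(reserve)))
    if len(levels) != 2:
        raise ValueError(f"reserve must have exactly 2 levels, got {levels}")
    counts = pd.Series(reserve).value_counts()
    if counts.min() < 2:
        raise ValueError("each reserve level needs at least 2 sites")
    indicator = (np.asarray(reserve) == levels[1]).astype(float)
    X = np.column_stack([np.ones(len(predictor)), predictor, indicator])
    return X, str(levels[1])


def _numeric_hessian(fun, p: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    k = len(p)
    h = rel_step * (1.0 + np.abs(p))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = p.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = fun(pp)
            pm = p.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = fun(pm)
            mp = p.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = fun(mp)
            mm = p.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = fun(mm)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_glm(richness, predictor, reserve, family: str = "poisson") -> GLMFit:
    """Maximum-likelihood count GLM: richness ~ predictor + reserve.

    The predictor is used as given (z-score upstream); the reserve
    factor becomes a 0/1 indicator with the lexicographically first
    level as reference. Shape parameters are profiled on an
    unconstrained scale with several starts (Poisson solution as warm
    start). Raises on non-convergence or when n <= k + 1 (AICc
    undefined).
    """
    y = np.asarray(richness, dtype=np.float64)
    x = np.asarray(predictor, dtype=np.float64)
    X, _ = _design(x, reserve)
    n = len(y)

    def negll_poisson(beta):
        eta = X @ beta
        if np.any(eta > 50):
            return 1e12
        return -float(np.sum(_poisson_ll(y, np.exp(eta))))

    beta0 = np.array([np.log(max(y.mean(), 0.1)), 0.0, 0.0])
    pois = optimize.minimize(negll_poisson, beta0, method="BFGS",
                             options={"gtol": 1e-8, "maxiter": 500})
    if family == "poisson":
        best, shape, negll = pois, None, negll_poisson
        converged = bool(pois.success or np.linalg.norm(pois.jac) < 1e-3)
    else:
        to_shape, starts = _shape_transform(family)

        def negll(params):
            eta = X @ params[:3]
            if np.any(eta > 50):
                return 1e12
            try:
                return -family_loglik(family, y, np.exp(eta), to_shape(params[3]))
            except (ValueError, FloatingPointError):
                return 1e12

        best = None
        for s0 in starts:
            start = np.append(pois.x, s0)
            res = optimize.minimize(negll, start, method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-9,
                                             "maxiter": 1200})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"{family} fit did not converge: {best}")
        converged = bool(best.fun < 1e11)
        shape = float(to_shape(best.x[3]))

    if not converged:
        raise RuntimeError(
            f"{family} fit did not converge: {getattr(best, 'message', '')}")
    params = best.x
    k = len(params)
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    ll = -float(best.fun)
    mu = np.exp(X @ params[:3])

    fun = negll if family != "poisson" else negll_poisson
    slope_se = np.nan
    for rel_step in (1e-5, 1e-4, 1e-3):  # widen if the surface is flat
        try:
            cov = np.linalg.pinv(_numeric_hessian(fun, params, rel_step))
            cand = float(np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else np.nan
        except np.linalg.LinAlgError:
            cand = np.nan
        if np.isfinite(cand):
            slope_se = cand
            break
    if slope_se > 0 and np.isfinite(slope_se):
        z = params[1] / slope_se
        p_value = float(2.0 * norm.sf(abs(z)))
    else:
        p_value = np.nan

    var = _family_variance(family, mu, shape)
    # residual df counts mean-model parameters only (shape parameters
    # do not consume residual degrees of freedom)
    dispersion = float(np.sum((y - mu) ** 2 / var) / (n - 3))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    efron = float(1.0 - np.sum((y - mu) ** 2) / ss_tot) if ss_tot > 0 else np.nan
    aic = 2.0 * k - 2.0 * ll
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    coef = {"intercept": float(params[0]), "slope": float(params[1]),
            "reserve": float(params[2])}
    return GLMFit(family=family, coefficients=coef, shape=shape,
                  log_likelihood=ll, aic=aic, aicc=aicc,
                  pearson_dispersion=dispersion, slope_se=slope_se,
                  slope_p_value=p_value, efron_r2=efron, n=n, k=k,
                  converged=converged, fitted_mu=mu)


# ---------------------------------------------------------------------------
# Selection


@dataclass
class ModelSelectionResult:
    """Per-family fits, the selected fit, and the decision trace."""

    fits: dict[str, GLMFit]
    selected: GLMFit
    trace: list[str]


def select_model(fits) -> ModelSelectionResult:
    """AIC-minimal fit; delta-AIC < 2 ties go to dispersion closest to 1."""
    if isinstance(fits, dict):
        fit_map = {k: v for k, v in fits.items() if v is not None}
    else:
        fit_map = {f.family: f for f in fits if f is not None}
    if not fit_map:
        raise ValueError("select_model needs at least one converged fit")
    trace: list[str] = []
    aics = {fam: f.aic for fam, f in fit_map.items()}
    best_aic = min(aics.values())
    candidates = [fam for fam, a in aics.items() if a - best_aic < 2.0]
    trace.append("AIC: " + ", ".join(f"{fam}={a:.2f}" for fam, a in aics.items()))
    if len(candidates) == 1:
        chosen = candidates[0]
        trace.append(f"selected {chosen} by minimum AIC (no tie)")
    else:
        chosen = min(candidates,
                     key=lambda fam: abs(fit_map[fam].pearson_dispersion - 1.0))
        trace.append(
            f"delta-AIC < 2 tie among {candidates}; selected {chosen} with "
            f"dispersion {fit_map[chosen].pearson_dispersion:.3f} closest to 1")
    return ModelSelectionResult(fits=fit_map, selected=fit_map[chosen], trace=trace)


def _predictor_label(components) -> str:
    if isinstance(components, str):
        return components.upper()
    return "z(" + "+".join(c.upper() for c in components) + ")"


def fit_and_select(y, predictor, reserve,
                   families=FAMILIES) -> ModelSelectionResult:
    """Fit every requested family and apply the AIC selection rule."""
    fits = {}
    for fam in families:
        try:
            fits[fam] = fit_glm(y, predictor, reserve, family=fam)
        except (RuntimeError, ValueError):
            continue
    return select_model(fits)


def run_model_grid(site_means: pd.DataFrame, richness: pd.DataFrame,
                   reserve_of_site, families=FAMILIES,
                   responses=("biophony", "insects", "frogs_birds_mammals"),
                   ) -> pd.DataFrame:
    """Selected-model report over responses x predictors x dataset variants.

    ``site_means`` is the per-variant site-mean index table
    (columns dataset_tag, site_id, act, aei, hf, sm); ``richness`` the
    accumulated-richness table from the annotation module. One row per
    combination: dataset, response, predictor, family, p_value,
    efron_r2, aicc, slope — sorted by AICc within dataset x response.
    """
    rich_by = {grp: sub.set_index("site_id")["accumulated_richness"]
               for grp, sub in richness.groupby("group")}
    rows = []
    for tag, sub in site_means.groupby("dataset_tag"):
        idx = sub.set_index("site_id")[list(SINGLE_PREDICTORS)].sort_index()
        sites = idx.index
        reserve = [reserve_of_site[s] for s in sites]
        predictors: list[tuple[str, np.ndarray]] = []
        for single in SINGLE_PREDICTORS:
            z, _, _ = zscore(idx[single].to_numpy(), name=single)
            predictors.append((_predictor_label(single), z))
        for comps in COMPOSITE_PREDICTORS:
            comp, _ = make_composite(idx, comps)
            predictors.append((_predictor_label(comps), comp.to_numpy()))
        for resp in responses:
            y = rich_by[resp].loc[sites].to_numpy()
            for label, pred in predictors:
                sel = fit_and_select(y, pred, reserve, families=families)
                f = sel.selected
                rows.append({"dataset": tag, "response": resp,
                             "predictor": label, "family": f.family,
                             "p_value": f.slope_p_value,
                             "efron_r2": f.efron_r2, "aicc": f.aicc,
                             "slope": f.coefficients["slope"]})
    report = pd.DataFrame(rows)
    return (report.sort_values(["dataset", "response", "aicc"])
            .reset_index(drop=True))


def poisson_r2_callback(site_sm: pd.Series, richness: pd.Series,
                        reserve: pd.Series) -> float:
    """Efron R² of a Poisson GLM richness ~ z(Sm) + reserve.

    The model-performance callback used by the Sm threshold scan; a
    single fast family keeps the 51-point screen cheap, and Efron's R²
    depends on the fitted means, which the log-link families share.
    """
    z, _, _ = zscore(site_sm.to_numpy(), name="sm")
    fit = fit_glm(richness.to_numpy(), z, reserve.to_numpy(), family="poisson")
    return fit.efron_r2
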