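"""Pooling of effect sizes with heterogeneity-gated model selection.

For each factor the pooled effect RR_++ is first computed under a
fixed-effects model (weights 1/v).  If the Q test for total heterogeneity is
significant at alpha, the between-study variance tau^2 is estimated by the
DerSimonian-Laird method of moments and the effect re-pooled under a
mixed-effects model (weights 1/(v + tau^2)).  Confidence intervals come from
a bias-corrected (BC) nonparametric bootstrap that resamples observations
and re-runs the whole select-and-pool decision in every resample; an effect
is declared significant when the BC interval excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effect_size import percent_change

__all__ = [
    "HeterogeneityResult",
    "PooledEffect",
    "GaussianFit",
    "pool_fixed",
    "q_test",
    "tau2_dl",
    "pool_mixed",
    "select_and_pool",
    "bootstrap_ci",
    "fit_gaussian",
    "pool_factor",
    "DEFAULT_BOOTSTRAP_ITERATIONS",
]

log = logging.getLogger(__name__)

#: Production default for the bootstrap; tests and quick runs pass fewer.
DEFAULT_BOOTSTRAP_ITERATIONS = 64_999


@dataclass(frozen=True)
class HeterogeneityResult:
    q_total: float
    df: int
    p_value: float
    significant: bool


@dataclass(frozen=True)
class GaussianFit:
    """Maximum-likelihood normal fit of the unweighted lnRR values."""

    mu: float
    sigma: float
    n: int


@dataclass(frozen=True)
class PooledEffect:
    factor: str
    k_obs: int
    model: str  # "fixed" or "mixed"
    rr_pp: float
    se_param: float
    tau2: float
    ci_low: float
    ci_high: float
    percent_change: float
    significant: bool
    heterogeneity: HeterogeneityResult


def _as_arrays(log_rr, v) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(log_rr, dtype=float)
    vv = np.asarray(v, dtype=float)
    if y.shape != vv.shape or y.ndim != 1:
        raise ValueError("log_rr and v must be 1-D arrays of equal length")
    if np.any(vv <= 0):
        raise ValueError("all variances must be positive")
    return y, vv


def pool_fixed(log_rr, v) -> tuple[float, float]:
    """Fixed-effects pooled estimate and its variance.

    rr_pp = sum(w_i y_i) / sum(w_i) with w = 1/v; variance = 1/sum(w).
    """
    y, vv = _as_arrays(log_rr, v)
    if y.size < 2:
        raise ValueError("pooling requires at least 2 effects")
    w = 1.0 / vv
    sw = w.sum()
    return float((w * y).sum() / sw), float(1.0 / sw)


def q_test(log_rr, v, rr_pp: float, alpha: float = 0.05) -> HeterogeneityResult:
    """Cochran's Q against chi-square with k-1 df."""
    y, vv = _as_arrays(log_rr, v)
    w = 1.0 / vv
    q = float((w * (y - rr_pp) ** 2).sum())
    df = y.size - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return HeterogeneityResult(q_total=q, df=df, p_value=p, significant=p < alpha)


def tau2_dl(q: float, weights) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    tau^2 = max(0, (Q - df) / c) with c = sum(w) - sum(w^2)/sum(w),
    truncated at zero.  A degenerate c <= 0 (all weight on one effect)
    returns 0 with a warning.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    df = w.size - 1
    c = w.sum() - (w**2).sum() / w.sum()
    if c <= 0:
        log.warning("degenerate weight distribution (c=%g); tau2 set to 0", c)
        return 0.0
    return float(max(0.0, (q - df) / c))


def pool_mixed(log_rr, v, tau2: float) -> tuple[float, float]:
    """Mixed-effects pooled estimate with weights 1/(v + tau^2)."""
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    y, vv = _as_arrays(log_rr, v)
    return pool_fixed(y, vv + tau2)


def select_and_pool(log_rr, v, alpha: float = 0.05, factor: str = "") -> PooledEffect:
    """Fixed-effects pooling, upgraded to mixed-effects when Q is significant.

    The returned CI fields are NaN; :func:`bootstrap_ci` fills them via
    :func:`pool_factor`.
    """
    y, vv = _as_arrays(log_rr, v)
    rr_fixed, var_fixed = pool_fixed(y, vv)
    het = q_test(y, vv, rr_fixed, alpha)
    if het.significant:
        t2 = tau2_dl(het.q_total, 1.0 / vv)
        rr_pp, var_pp = pool_mixed(y, vv, t2)
        model = "mixed"
    else:
        t2, rr_pp, var_pp, model = 0.0, rr_fixed, var_fixed, "fixed"
    return PooledEffect(
        factor=factor,
        k_obs=int(y.size),
        model=model,
        rr_pp=rr_pp,
        se_param=float(np.sqrt(var_pp)),
        tau2=t2,
        ci_low=float("nan"),
        ci_high=float("nan"),
        percent_change=float(percent_change(rr_pp)),
        significant=False,
        heterogeneity=het,
    )


def _pooled_estimates_vectorized(y: np.ndarray, v: np.ndarray, alpha: float) -> np.ndarray:
    """Select-and-pool point estimate for each row of (B, k) resample matrices."""
    w = 1.0 / v
    sw = w.sum(axis=1)
    fixed = (w * y).sum(axis=1) / sw
    q = (w * (y - fixed[:, None]) ** 2).sum(axis=1)
    df = y.shape[1] - 1
    p = stats.chi2.sf(q, df)
    c = sw - (w**2).sum(axis=1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(c > 0, np.maximum(0.0, (q - df) / c), 0.0)
    heterogeneous = p < alpha
    wm = 1.0 / (v + tau2[:, None])
    mixed = (wm * y).sum(axis=1) / wm.sum(axis=1)
    return np.where(heterogeneous, mixed, fixed)


def bootstrap_ci(
    log_rr,
    v,
    b: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    study_id=None,
) -> tuple[float, float]:
    """Bias-corrected bootstrap confidence interval for the pooled effect.

    Observations are resampled with replacement (same k) and the full
    select-and-pool pipeline — Q test, tau^2, model choice — is re-run in
    every resample.  The bias-correction constant is
    z0 = Phi^-1(prop of bootstrap estimates strictly below the original),
    and the interval endpoints are the bootstrap quantiles at
    Phi(2 z0 -/+ z_{1-alpha/2}).  Passing ``study_id`` switches to a
    study-level cluster bootstrap (whole studies resampled).
    """
    y, vv = _as_arrays(log_rr, v)
    if y.size < 2:
        raise ValueError("bootstrap requires at least 2 effects")
    if b < 999:
        raise ValueError("at least 999 bootstrap iterations required")
    rng = np.random.default_rng(seed)
    theta_hat = select_and_pool(y, vv, alpha).rr_pp

    if study_id is None:
        idx = rng.integers(0, y.size, size=(b, y.size))
    else:
        sid = np.asarray(study_id)
        studies, inverse = np.unique(sid, return_inverse=True)
        members = [np.flatnonzero(inverse == s) for s in range(studies.size)]
        draws = rng.integers(0, studies.size, size=(b, studies.size))
        idx_rows = [np.concatenate([members[j] for j in row]) for row in draws]
        # ragged rows: fall back to a per-row loop
        boot = np.empty(b)
        for i, rows in enumerate(idx_rows):
            boot[i] = _pooled_estimates_vectorized(
                y[rows][None, :], vv[rows][None, :], alpha
            )[0]
        return _bc_interval(boot, theta_hat, alpha)

    boot = _pooled_estimates_vectorized(y[idx], vv[idx], alpha)
    return _bc_interval(boot, theta_hat, alpha)


def _bc_interval(boot: np.ndarray, theta_hat: float, alpha: float) -> tuple[float, float]:
    b = boot.size
    if np.ptp(boot) == 0.0:
        log.warning("degenerate bootstrap distribution; interval collapses to a point")
        return float(boot[0]), float(boot[0])
    prop = np.count_nonzero(boot < theta_hat) / b  # strictly-less-than convention
    prop = min(max(prop, 1.0 / (2 * b)), 1.0 - 1.0 / (2 * b))
    z0 = stats.norm.ppf(prop)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    lo_q = stats.norm.cdf(2 * z0 - z_crit)
    hi_q = stats.norm.cdf(2 * z0 + z_crit)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


def fit_gaussian(log_rr) -> GaussianFit:
    """ML normal fit (mean, SD with 1/n) of the unweighted lnRR values."""
    y = np.asarray(log_rr, dtype=float)
    if y.size < 2:
        raise ValueError("Gaussian fit requires at least 2 values")
    sigma = float(np.std(y))
    if sigma == 0.0:
        log.warning("all lnRR values identical; sigma = 0")
    return GaussianFit(mu=float(np.mean(y)), sigma=sigma, n=int(y.size))


def pool_factor(
    log_rr,
    v,
    factor: str = "",
    alpha: float = 0.05,
    b: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int | np.random.Generator | None = None,
    study_id=None,
) -> PooledEffect:
    """Full per-factor analysis: select-and-pool plus bias-corrected CI."""
    pooled = select_and_pool(log_rr, v, alpha, factor=factor)
    lo, hi = bootstrap_ci(log_rr, v, b=b, alpha=alpha, seed=seed, study_id=study_id)
    significant = lo > 0.0 or hi < 0.0
    return PooledEffect(
        factor=pooled.factor,
        k_obs=pooled.k_obs,
        model=pooled.model,
        rr_pp=pooled.rr_pp,
        se_param=pooled.se_param,
        tau2=pooled.tau2,
        ci_low=lo,
        ci_high=hi,
        percent_change=pooled.percent_change,
        significant=significant,
        heterogeneity=pooled.heterogeneity,
    )
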