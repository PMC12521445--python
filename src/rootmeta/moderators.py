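"""Subgroup meta-analysis by incubation duration and meta-regression.

Duration-grouped analysis bins effects into half-open intervals, pools each
bin that has enough independent evidence (>= 3 distinct studies or >= 10
observations), and decomposes the total heterogeneity Q into between- and
within-group components under common fixed-effects weights.  Continuous
moderators (duration, geoclimate, litter chemistry) are tested with a
random-effects weighted meta-regression, with the residual-based method of
moments supplying the between-study variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import PooledEffect, pool_factor

__all__ = [
    "DEFAULT_DURATION_EDGES",
    "SubgroupResult",
    "QPartition",
    "MetaRegressionResult",
    "bin_by_duration",
    "subgroup_analysis",
    "meta_regress",
]

log = logging.getLogger(__name__)

#: Default duration bin edges in months; configurable per run.
DEFAULT_DURATION_EDGES = (4.0, 6.0, 12.0, 18.0, 24.0)

#: Minimum evidence for a subgroup to be pooled.
MIN_STUDIES = 3
MIN_OBS = 10


@dataclass(frozen=True)
class SubgroupResult:
    factor: str
    group_label: str
    n_studies: int
    n_obs: int
    included: bool
    pooled: PooledEffect | None


@dataclass(frozen=True)
class QPartition:
    q_total: float
    q_between: float
    q_within_sum: float
    df_between: int
    df_within: int
    p_between: float


@dataclass(frozen=True)
class MetaRegressionResult:
    factor: str
    moderator_name: str
    slope: float
    intercept: float
    slope_se: float
    tau2: float
    qm: float
    p_value: float
    n_obs: int


def bin_by_duration(durations, edges=DEFAULT_DURATION_EDGES) -> np.ndarray:
    """Assign each duration to a half-open bin label.

    With edges (e0, ..., em) the bins are ``<e0``, ``[e_i, e_{i+1})`` and an
    open-ended ``>=em``; every value lands in exactly one bin.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) == 0:
        raise ValueError("at least one bin edge required")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    d = np.asarray(durations, dtype=float)
    labels = np.empty(d.shape, dtype=object)
    labels[d < edges[0]] = f"<{edges[0]:g}"
    for a, b in zip(edges, edges[1:]):
        labels[(d >= a) & (d < b)] = f"[{a:g},{b:g})"
    labels[d >= edges[-1]] = f">={edges[-1]:g}"
    return labels


def _bin_order(edges) -> list[str]:
    edges = tuple(float(e) for e in edges)
    out = [f"<{edges[0]:g}"]
    out += [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
    out.append(f">={edges[-1]:g}")
    return out


def subgroup_analysis(
    effects: pd.DataFrame,
    edges=DEFAULT_DURATION_EDGES,
    alpha: float = 0.05,
    b: int = 1999,
    seed: int | np.random.Generator | None = None,
    factor: str = "",
) -> tuple[list[SubgroupResult], QPartition | None]:
    """Duration-binned subgroup meta-analysis for one factor's effects.

    ``effects`` needs columns ``log_rr, v, study_id, duration_months``.
    Groups with fewer than 3 independent studies and fewer than 10
    observations are flagged ``included=False`` and not pooled.  The Q
    partition (Q_total = Q_between + sum of Q_within under common
    fixed-effects weights) is computed over the included groups only;
    ``p_between`` tests group-mean differences on chi-square df G-1.
    """
    rng = np.random.default_rng(seed)
    labels = bin_by_duration(effects["duration_months"].to_numpy(), edges)
    results: list[SubgroupResult] = []
    included_masks: list[np.ndarray] = []
    for lab in _bin_order(edges):
        mask = labels == lab
        n_obs = int(mask.sum())
        if n_obs == 0:
            continue
        n_studies = int(effects.loc[mask, "study_id"].nunique())
        included = n_studies >= MIN_STUDIES or n_obs >= MIN_OBS
        pooled = None
        if included and n_obs >= 2:
            pooled = pool_factor(
                effects.loc[mask, "log_rr"].to_numpy(),
                effects.loc[mask, "v"].to_numpy(),
                factor=factor,
                alpha=alpha,
                b=b,
                seed=rng,
            )
        elif included:
            included = False  # a single observation cannot be pooled
        results.append(
            SubgroupResult(
                factor=factor,
                group_label=lab,
                n_studies=n_studies,
                n_obs=n_obs,
                included=included,
                pooled=pooled,
            )
        )
        if included:
            included_masks.append(mask)

    if not included_masks:
        log.warning("no subgroup met the inclusion rule; Q partition skipped")
        return results, None
    partition = _q_partition(effects, included_masks)
    return results, partition


def _q_partition(effects: pd.DataFrame, masks: list[np.ndarray]) -> QPartition:
    """Decompose fixed-effects Q over the included groups."""
    all_mask = np.logical_or.reduce(masks)
    y = effects.loc[all_mask, "log_rr"].to_numpy()
    w = 1.0 / effects.loc[all_mask, "v"].to_numpy()
    grand = (w * y).sum() / w.sum()
    q_total = float((w * (y - grand) ** 2).sum())
    q_within = 0.0
    q_between = 0.0
    for mask in masks:
        yg = effects.loc[mask, "log_rr"].to_numpy()
        wg = 1.0 / effects.loc[mask, "v"].to_numpy()
        mg = (wg * yg).sum() / wg.sum()
        q_within += float((wg * (yg - mg) ** 2).sum())
        q_between += float(wg.sum() * (mg - grand) ** 2)
    df_between = len(masks) - 1
    df_within = int(all_mask.sum()) - len(masks)
    p_between = float(stats.chi2.sf(q_between, df_between)) if df_between > 0 else 1.0
    return QPartition(
        q_total=q_total,
        q_between=q_between,
        q_within_sum=q_within,
        df_between=df_between,
        df_within=df_within,
        p_between=p_between,
    )


def meta_regress(
    effects: pd.DataFrame,
    moderator_name: str,
    alpha: float = 0.05,
    factor: str = "",
) -> MetaRegressionResult:
    """Random-effects weighted regression of lnRR on one moderator.

    Fit sequence: (1) fixed-effects WLS (weights 1/v) gives the residual
    heterogeneity Q_E; (2) the method-of-moments estimator generalising
    DerSimonian-Laird to a design matrix,

        tau^2 = max(0, (Q_E - (k - p)) / (tr(W) - tr((X'WX)^-1 X'W^2 X))),

    yields the between-study variance; (3) the final fit uses weights
    1/(v + tau^2).  QM = (slope/se)^2 is referred to chi-square with 1 df.
    """
    if moderator_name not in effects.columns:
        raise KeyError(f"moderator {moderator_name!r} not in effects table")
    sub = effects.loc[effects[moderator_name].notna(), ["log_rr", "v", moderator_name]]
    if len(sub) < 4:
        raise ValueError(
            f"meta-regression needs >= 4 effects with {moderator_name!r}, got {len(sub)}"
        )
    x = sub[moderator_name].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"moderator {moderator_name!r} is constant")
    y = sub["log_rr"].to_numpy()
    v = sub["v"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    k, p = X.shape

    beta_f, _ = _wls(X, y, 1.0 / v)
    resid = y - X @ beta_f
    q_e = float(((1.0 / v) * resid**2).sum())
    tau2 = _tau2_mom_regression(X, v, q_e)

    w_star = 1.0 / (v + tau2)
    beta, cov = _wls(X, y, w_star)
    slope = float(beta[1])
    slope_se = float(np.sqrt(cov[1, 1]))
    qm = (slope / slope_se) ** 2
    p_value = float(stats.chi2.sf(qm, 1))
    return MetaRegressionResult(
        factor=factor,
        moderator_name=moderator_name,
        slope=slope,
        intercept=float(beta[0]),
        slope_se=slope_se,
        tau2=tau2,
        qm=float(qm),
        p_value=p_value,
        n_obs=k,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares; returns (beta, covariance of beta)."""
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    cov = np.linalg.inv(xtwx)
    beta = cov @ (Xw.T @ y)
    return beta, cov


def _tau2_mom_regression(X: np.ndarray, v: np.ndarray, q_e: float) -> float:
    """Method-of-moments tau^2 from the residual Q of a fixed-effects fit."""
    k, p = X.shape
    w = 1.0 / v
    Xw = X * w[:, None]
    xtwx_inv = np.linalg.inv(X.T @ Xw)
    trace_correction = np.trace(xtwx_inv @ (X.T @ (X * (w**2)[:, None])))
    denom = w.sum() - trace_correction
    if denom <= 0:
        log.warning("degenerate meta-regression weights; tau2 set to 0")
        return 0.0
    return float(max(0.0, (q_e - (k - p)) / denom))
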