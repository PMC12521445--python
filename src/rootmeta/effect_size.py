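"""Per-observation effect sizes: log response ratio, variance, weight.

The effect metric is the natural log of the treatment/control mean ratio,

    lnRR = ln(X_t / X_c),

with sampling variance

    v = S_t^2 / (n_t X_t^2) + S_c^2 / (n_c X_c^2)

and inverse-variance weight w = 1/v.  The percent-change transform
``(e^x - 1) * 100`` maps a pooled lnRR back onto the mass-loss scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MODERATOR_COLUMNS, GroupSummary

__all__ = [
    "EffectSize",
    "log_response_ratio",
    "effect_variance",
    "weight",
    "percent_change",
    "compute_effects",
    "ZERO_VARIANCE_FLOOR",
]

log = logging.getLogger(__name__)

#: Variance floor for observations whose resolved SDs are both zero.
#: True zero dispersion is an artifact of reporting, not of the field data;
#: flooring avoids an infinite weight swallowing the analysis.
ZERO_VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class EffectSize:
    """One observation's effect size triple plus carried-through metadata."""

    obs_id: str
    log_rr: float
    v: float
    w: float
    factor: str
    duration_months: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("variance must be positive")
        if not np.isclose(self.w * self.v, 1.0, rtol=1e-12):
            raise ValueError("weight must equal 1/v")


def log_response_ratio(x_t: float, x_c: float) -> float:
    """ln(x_t / x_c); antisymmetric under swapping the groups."""
    if not x_t > 0:
        raise ValueError(f"treatment mean must be positive, got {x_t}")
    if not x_c > 0:
        raise ValueError(f"control mean must be positive, got {x_c}")
    return float(np.log(x_t) - np.log(x_c))


def effect_variance(t: GroupSummary, c: GroupSummary, sd_t: float, sd_c: float) -> float:
    """Sampling variance of lnRR from the two group summaries.

    ``sd_t``/``sd_c`` are the *resolved* standard deviations (see
    :func:`rootmeta.dataset.resolve_sd`).  Scale-free: rescaling mass loss
    units rescales the SDs with the means and leaves v unchanged.
    """
    if t.mean_mass_loss <= 0 or c.mean_mass_loss <= 0:
        raise ValueError("group means must be positive for a ratio variance")
    return float(
        sd_t**2 / (t.n * t.mean_mass_loss**2) + sd_c**2 / (c.n * c.mean_mass_loss**2)
    )


def weight(v: float) -> float:
    """Inverse-variance weight 1/v."""
    if v <= 0:
        raise ValueError(f"variance must be positive, got {v}")
    return 1.0 / v


def percent_change(rr_pp: float | np.ndarray) -> float | np.ndarray:
    """(e^x - 1) * 100: pooled lnRR on the percent mass-loss scale."""
    return (np.exp(rr_pp) - 1.0) * 100.0


def compute_effects(harmonized: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compute the effects table from a harmonized observation table.

    Control-only rows and rows where either mean is nonpositive are
    excluded (counted in the report).  Zero-variance observations are
    floored at :data:`ZERO_VARIANCE_FLOOR` with a logged warning.

    Returns ``(effects, report)`` where ``effects`` has columns
    ``obs_id, study_id, site_id, factor, log_rr, v, w, duration_months``
    plus the moderator columns.
    """
    df = harmonized
    report: dict[str, int] = {}
    paired = df["treatment_mean"].notna()
    report["excluded_control_only"] = int((~paired).sum())
    df = df.loc[paired]
    positive = (df["treatment_mean"] > 0) & (df["control_mean"] > 0)
    report["excluded_nonpositive_mean"] = int((~positive).sum())
    df = df.loc[positive]

    log_rr = np.log(df["treatment_mean"].to_numpy() / df["control_mean"].to_numpy())
    v = df["treatment_sd"].to_numpy() ** 2 / (
        df["treatment_n"].to_numpy() * df["treatment_mean"].to_numpy() ** 2
    ) + df["control_sd"].to_numpy() ** 2 / (
        df["control_n"].to_numpy() * df["control_mean"].to_numpy() ** 2
    )
    floored = v < ZERO_VARIANCE_FLOOR
    if floored.any():
        log.warning("flooring %d zero-variance observation(s) at %g",
                    int(floored.sum()), ZERO_VARIANCE_FLOOR)
    report["variance_floored"] = int(floored.sum())
    v = np.maximum(v, ZERO_VARIANCE_FLOOR)

    effects = pd.DataFrame(
        {
            "obs_id": df["obs_id"].to_numpy(),
            "study_id": df["study_id"].to_numpy(),
            "site_id": df["site_id"].to_numpy(),
            "factor": df["factor"].to_numpy(),
            "log_rr": log_rr,
            "v": v,
            "w": 1.0 / v,
        }
    )
    for col in MODERATOR_COLUMNS:
        effects[col] = df[col].to_numpy()
    report["effects_out"] = len(effects)
    return effects.reset_index(drop=True), report
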