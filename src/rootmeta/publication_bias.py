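"""Publication-bias assessment via Rosenthal's fail-safe number.

The fail-safe number N_fs is the count of hypothetical null-result studies
that would have to exist, unpublished, to dilute a pooled effect to
one-tailed nonsignificance under Stouffer's combined-z rule:

    N_fs = (sum z_i)^2 / z_c^2 - k,   z_i = lnRR_i / sqrt(v_i),

with z_c = 1.645 (one-tailed alpha = 0.05) and truncation at zero.  An
analysis is considered robust to publication bias when N_fs strictly
exceeds 5n + 10 for n observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FailSafeResult", "fail_safe_n", "robustness", "assess"]

#: One-tailed critical z at alpha = 0.05.
Z_CRIT_ONE_TAILED = float(stats.norm.ppf(0.95))


@dataclass(frozen=True)
class FailSafeResult:
    factor: str
    n_obs: int
    n_fs: float
    threshold: float
    robust: bool


def fail_safe_n(log_rr, v) -> float:
    """Rosenthal fail-safe number for one factor's effects."""
    y = np.asarray(log_rr, dtype=float)
    vv = np.asarray(v, dtype=float)
    if y.size < 2:
        raise ValueError("fail-safe number requires at least 2 effects")
    z = y / np.sqrt(vv)
    k = y.size
    return float(max(0.0, z.sum() ** 2 / Z_CRIT_ONE_TAILED**2 - k))


def robustness(n_fs: float, n_obs: int) -> bool:
    """Strict 5n + 10 rule; a tie counts as not robust."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    return n_fs > 5 * n_obs + 10


def assess(log_rr, v, factor: str = "") -> FailSafeResult:
    n_obs = int(np.asarray(log_rr).size)
    n_fs = fail_safe_n(log_rr, v)
    threshold = 5.0 * n_obs + 10.0
    return FailSafeResult(
        factor=factor,
        n_obs=n_obs,
        n_fs=n_fs,
        threshold=threshold,
        robust=robustness(n_fs, n_obs),
    )
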