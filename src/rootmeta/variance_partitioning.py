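"""Driver importance for control-condition mass loss.

This stage asks what controls decomposition where nothing is manipulated:
geoclimate (latitude, longitude, elevation, MAT, MAP) versus initial litter
quality (AUR, C, N, P, AUR:N, C:N).  It provides

* out-of-bag random-forest variance explained per predictor set, with a
  12-month temporal split (early vs late decomposition stages);
* permutation importances with response-permutation significance tests;
* PC1 composite scores per predictor group and Chevan-Sutherland
  hierarchical partitioning of linear-model R^2 between the groups;
* simple trait-mass-loss Pearson correlations.

The forest is a bagged ensemble of CART regression trees with explicit
bootstrap bookkeeping, so out-of-bag (OOB) predictions and OOB permutation
importances are exact and reproducible under a seed.  Rows are identified
by ``obs_id`` and fitted in canonical (sorted) order, so results do not
depend on input row order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "GEOCLIMATE_COLUMNS",
    "QUALITY_COLUMNS",
    "PredictorMatrix",
    "ImportanceResult",
    "PartitionResult",
    "build_matrix",
    "rf_variance_explained",
    "rf_permutation_importance",
    "group_mean_contribution",
    "pc1_composite",
    "hierarchical_partition",
    "trait_correlation",
]

log = logging.getLogger(__name__)

GEOCLIMATE_COLUMNS = ("latitude", "longitude", "elevation", "mat", "map")
QUALITY_COLUMNS = ("aur", "c", "n_conc", "p_conc", "aur_n", "c_n")

#: Sign anchors for PC1 orientation: scores increase with litter N and site MAT.
PC1_ANCHORS = {"quality": "n_conc", "geoclimate": "mat"}

DEFAULT_N_TREES = 500
DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class PredictorMatrix:
    """Complete-case predictor matrix over control-only observations."""

    X: pd.DataFrame  # indexed by obs_id, canonical sort order
    y: pd.Series  # mass loss %, same index
    column_set: str
    time_filter: str

    @property
    def n_rows(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ImportanceResult:
    predictor: str
    importance: float  # OOB error increase under permutation, % of Var(y)
    p_value: float | None
    significant: bool | None


@dataclass(frozen=True)
class PartitionResult:
    group: str
    independent_contribution: float
    total_model_r2: float


def build_matrix(
    harmonized: pd.DataFrame,
    column_set: str = "both",
    time_filter: str = "all",
) -> PredictorMatrix:
    """Assemble the control-only predictor matrix.

    ``column_set``: ``geoclimate``, ``quality`` or ``both``.  ``time_filter``:
    ``all``, ``le12`` (duration <= 12 months, boundary included) or ``gt12``.
    Incubation duration is always retained as a predictor.  Rows with any
    missing value in the chosen columns are dropped (complete-case rule).
    """
    cols = {"geoclimate": GEOCLIMATE_COLUMNS, "quality": QUALITY_COLUMNS,
            "both": GEOCLIMATE_COLUMNS + QUALITY_COLUMNS}
    if column_set not in cols:
        raise ValueError(f"unknown column set {column_set!r}")
    predictors = list(cols[column_set]) + ["duration_months"]

    df = harmonized.loc[harmonized["treatment_mean"].isna()]
    if time_filter == "le12":
        df = df.loc[df["duration_months"] <= 12.0]
    elif time_filter == "gt12":
        df = df.loc[df["duration_months"] > 12.0]
    elif time_filter != "all":
        raise ValueError(f"unknown time filter {time_filter!r}")

    df = df.loc[df["control_mean"].notna()]
    complete = df[predictors].notna().all(axis=1)
    df = df.loc[complete]
    if df.empty:
        raise ValueError(
            f"empty predictor matrix (set={column_set!r}, filter={time_filter!r})"
        )
    df = df.set_index("obs_id").sort_index()
    return PredictorMatrix(
        X=df[predictors].astype(float),
        y=df["control_mean"].astype(float),
        column_set=column_set,
        time_filter=time_filter,
    )


class _BaggedForest:
    """Regression forest with explicit bootstrap/OOB bookkeeping.

    One-third of the predictors are tried at each split (regression-forest
    convention).  Trees and bootstrap draws are derived from a seed sequence,
    so fits are fully reproducible.
    """

    def __init__(self, n_trees: int, seed) -> None:
        self.n_trees = n_trees
        self._ss = (
            seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaggedForest":
        n, p = X.shape
        max_features = max(1, math.ceil(p / 3))
        boot_ss, tree_ss = self._ss.spawn(2)
        rng = np.random.default_rng(boot_ss)
        tree_seeds = np.random.default_rng(tree_ss).integers(0, 2**31 - 1, self.n_trees)
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n)
            tree = DecisionTreeRegressor(
                max_features=max_features, random_state=int(tree_seeds[t])
            )
            tree.fit(X[idx], y[idx])
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self.trees.append(tree)
            self.oob_masks.append(oob)
        self._X, self._y = X, y
        return self

    def oob_prediction(self) -> np.ndarray:
        n = self._X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.any():
                total[oob] += tree.predict(self._X[oob])
                count[oob] += 1
        pred = np.full(n, np.nan)
        seen = count > 0
        pred[seen] = total[seen] / count[seen]
        return pred

    def oob_pseudo_r2(self) -> float:
        pred = self.oob_prediction()
        seen = ~np.isnan(pred)
        mse = float(np.mean((self._y[seen] - pred[seen]) ** 2))
        return 1.0 - mse / float(np.var(self._y))

    def oob_permutation_importance(self, perm_seed) -> np.ndarray:
        """Mean over trees of the OOB MSE increase when one predictor is
        permuted, expressed as a percentage of Var(y)."""
        n, p = self._X.shape
        rng = np.random.default_rng(perm_seed)
        increases = np.zeros(p)
        counts = np.zeros(p)
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            X_oob, y_oob = self._X[oob], self._y[oob]
            base_mse = np.mean((y_oob - tree.predict(X_oob)) ** 2)
            for j in range(p):
                Xp = X_oob.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm_mse = np.mean((y_oob - tree.predict(Xp)) ** 2)
                increases[j] += perm_mse - base_mse
                counts[j] += 1
        return 100.0 * (increases / counts) / float(np.var(self._y))


def rf_variance_explained(
    m: PredictorMatrix, n_trees: int = DEFAULT_N_TREES, seed: int | None = None
) -> float:
    """Out-of-bag pseudo-R^2 = 1 - MSE_oob / Var(y) of a regression forest."""
    if m.n_rows < 30:
        raise ValueError(f"need >= 30 rows for a forest fit, got {m.n_rows}")
    forest = _BaggedForest(n_trees, seed).fit(m.X.to_numpy(), m.y.to_numpy())
    return forest.oob_pseudo_r2()


def rf_permutation_importance(
    m: PredictorMatrix,
    n_trees: int = DEFAULT_N_TREES,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[ImportanceResult]:
    """OOB permutation importances with response-permutation p-values.

    The observed importance of a predictor is the mean OOB error increase
    when its values are permuted.  The null distribution comes from
    ``n_perm`` full refits with the *response* permuted; the p-value uses
    the add-one rule p = (1 + #{null >= observed}) / (n_perm + 1), so it is
    never exactly zero.  ``n_perm = 0`` skips significance testing.
    """
    if m.n_rows < 30:
        raise ValueError(f"need >= 30 rows for a forest fit, got {m.n_rows}")
    if 0 < n_perm < 20:
        log.warning("n_perm=%d is small; permutation p-values will be unstable", n_perm)
    ss = np.random.SeedSequence(seed)
    fit_ss, imp_ss, null_ss = ss.spawn(3)
    X, y = m.X.to_numpy(), m.y.to_numpy()
    forest = _BaggedForest(n_trees, fit_ss).fit(X, y)
    observed = forest.oob_permutation_importance(imp_ss)

    p_values: list[float | None] = [None] * X.shape[1]
    if n_perm > 0:
        null = np.empty((n_perm, X.shape[1]))
        children = null_ss.spawn(2 * n_perm + 1)
        null_rng = np.random.default_rng(children[0])
        pairs = list(zip(children[1::2], children[2::2]))
        for r, (refit_ss, rimp_ss) in enumerate(pairs):
            y_perm = null_rng.permutation(y)
            nf = _BaggedForest(n_trees, refit_ss).fit(X, y_perm)
            null[r] = nf.oob_permutation_importance(rimp_ss)
        p_values = [
            (1.0 + np.count_nonzero(null[:, j] >= observed[j])) / (n_perm + 1.0)
            for j in range(X.shape[1])
        ]
    return [
        ImportanceResult(
            predictor=col,
            importance=float(observed[j]),
            p_value=p_values[j],
            significant=None if p_values[j] is None else p_values[j] < alpha,
        )
        for j, col in enumerate(m.X.columns)
    ]


def group_mean_contribution(
    importances: list[ImportanceResult],
    grouping: dict[str, list[str]],
    scale_to_r2: float | None = None,
) -> dict[str, float]:
    """Arithmetic mean of per-predictor importances within each group.

    With ``scale_to_r2`` (a pseudo-R^2 fraction), importances are first
    rescaled so their sum equals the model's explained variance in percent;
    by default raw permutation importances are averaged.
    """
    by_name = {imp.predictor: imp.importance for imp in importances}
    for group, members in grouping.items():
        unknown = [mname for mname in members if mname not in by_name]
        if unknown:
            raise KeyError(f"unknown predictor(s) in group {group!r}: {unknown}")
    values = dict(by_name)
    if scale_to_r2 is not None:
        total = sum(values.values())
        if total <= 0:
            raise ValueError("cannot rescale nonpositive total importance")
        factor = 100.0 * scale_to_r2 / total
        values = {kk: vv * factor for kk, vv in values.items()}
    return {
        group: float(np.mean([values[mname] for mname in members]))
        for group, members in grouping.items()
    }


def pc1_composite(X: pd.DataFrame, anchor: str | None = None) -> np.ndarray:
    """First principal-component scores of the standardized columns.

    The score sign is fixed so the loading of ``anchor`` (default: first
    column) is positive, making composites reproducible across runs.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PC1 needs >= 3 rows and >= 2 columns")
    if X.isna().any().any():
        raise ValueError("PC1 requires complete cases")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        zero = list(X.columns[sd == 0])
        raise ValueError(f"zero-variance column(s): {zero}")
    Z = (arr - arr.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loading = vt[0]
    anchor_idx = 0 if anchor is None else list(X.columns).index(anchor)
    if loading[anchor_idx] < 0:
        loading = -loading
    return Z @ loading


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Linear-model R^2 via least squares (intercept included)."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant response")
    return 1.0 - float((resid**2).sum()) / tss


def hierarchical_partition(
    response, composites: dict[str, np.ndarray]
) -> list[PartitionResult]:
    """Chevan-Sutherland hierarchical partitioning over predictor groups.

    Fits linear models on every subset of the group composites and assigns
    each group the average R^2 increment over all orderings in which it can
    enter the model.  Independent contributions telescope: their sum equals
    the full-model R^2.
    """
    names = list(composites)
    g = len(names)
    if g < 2:
        raise ValueError("need at least 2 groups to partition")
    y = np.asarray(response, dtype=float)
    mats = {name: np.asarray(vec, dtype=float).reshape(len(y), -1) for name, vec in composites.items()}

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, g + 1):
        for subset in itertools.combinations(names, r):
            X = np.column_stack([mats[name] for name in subset])
            r2_cache[frozenset(subset)] = _r2(y, X)
    full_r2 = r2_cache[frozenset(names)]

    results = []
    for name in names:
        others = [o for o in names if o != name]
        ic = 0.0
        for r in range(0, g):
            coef = (
                math.factorial(r) * math.factorial(g - r - 1) / math.factorial(g)
            )
            for subset in itertools.combinations(others, r):
                inc = r2_cache[frozenset(subset) | {name}] - r2_cache[frozenset(subset)]
                ic += coef * inc
        results.append(
            PartitionResult(group=name, independent_contribution=ic, total_model_r2=full_r2)
        )
    return results


def trait_correlation(
    harmonized: pd.DataFrame, trait: str
) -> tuple[float, float, int]:
    """Pearson correlation of control mass loss with one litter trait.

    Uses control-only rows with the trait present; returns (r, p, n) with a
    two-tailed t-test p-value.
    """
    df = harmonized.loc[harmonized["treatment_mean"].isna()]
    sub = df.loc[df[trait].notna() & df["control_mean"].notna(), [trait, "control_mean"]]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete pairs for trait {trait!r}")
    x = sub[trait].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"trait {trait!r} is constant")
    r, p = stats.pearsonr(x, sub["control_mean"].to_numpy(dtype=float))
    return float(r), float(p), len(sub)
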