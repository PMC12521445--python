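"""End-to-end orchestration: ingest -> effects -> pooling -> moderators ->
publication bias -> variance partitioning, with a consolidated report.

Everything is driven by a :class:`PipelineConfig` (YAML-loadable); a run
writes every stage's table plus ``report.json`` and a ``manifest.json``
recording the seed, a config hash and row-count reconciliation.  Identical
config + seed reproduce ``report.json`` byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset, effect_size, moderators, pooling, publication_bias
from . import variance_partitioning as vp

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str = "observations.csv"
    out_dir: str = "rootmeta_out"
    alpha: float = 0.05
    bootstrap_iterations: int = pooling.DEFAULT_BOOTSTRAP_ITERATIONS
    seed: int = 0
    duration_edges: tuple[float, ...] = moderators.DEFAULT_DURATION_EDGES
    n_trees: int = vp.DEFAULT_N_TREES
    n_perm: int = vp.DEFAULT_N_PERM
    meta_regression_moderators: tuple[str, ...] = (
        "duration_months",
        "mat",
        "map",
        "aur",
        "n_conc",
        "aur_n",
    )
    column_groups: dict = field(
        default_factory=lambda: {
            "geoclimate": list(vp.GEOCLIMATE_COLUMNS),
            "quality": list(vp.QUALITY_COLUMNS),
        }
    )
    scale_importance_to_r2: bool = False
    cluster_bootstrap: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.bootstrap_iterations < 999:
            raise ValueError("bootstrap_iterations must be >= 999")
        self.duration_edges = tuple(float(e) for e in self.duration_edges)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name: str, t0: float, n_in: int, n_out: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d seconds=%.2f", name, n_in, n_out,
             time.perf_counter() - t0)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    ss_pool, ss_subgroup, ss_forest = rng_root.spawn(3)

    # ingest + harmonize
    t0 = time.perf_counter()
    ingest = dataset.read_observations(config.input_path)
    harmonized, ingest_report = dataset.harmonize(ingest.table)
    ingest_report["rows_quarantined"] = len(ingest.quarantined)
    ingest_report["issues"] = [f"row {i}: {msg}" for i, msg in ingest.issues]
    harmonized.to_csv(out / "harmonized.csv", index=False)
    dataset.write_ingest_report(ingest_report, out / "ingest_report.json")
    _stage("ingest", t0, len(ingest.table) + len(ingest.quarantined), len(harmonized))

    # effect sizes
    t0 = time.perf_counter()
    effects, effects_report = effect_size.compute_effects(harmonized)
    effects.to_csv(out / "effects.csv", index=False)
    _stage("effects", t0, len(harmonized), len(effects))

    # per-factor pooling
    t0 = time.perf_counter()
    pooled_rows = []
    pooled_by_factor: dict[str, pooling.PooledEffect] = {}
    gaussian_fits = {}
    factors = [f for f in dataset.FACTORS if (effects["factor"] == f).sum() >= 2]
    pool_children = ss_pool.spawn(len(factors))
    for factor, child in zip(factors, pool_children):
        sub = effects.loc[effects["factor"] == factor]
        pe = pooling.pool_factor(
            sub["log_rr"].to_numpy(),
            sub["v"].to_numpy(),
            factor=factor,
            alpha=config.alpha,
            b=config.bootstrap_iterations,
            seed=np.random.default_rng(child),
            study_id=sub["study_id"].to_numpy() if config.cluster_bootstrap else None,
        )
        pooled_by_factor[factor] = pe
        gaussian_fits[factor] = pooling.fit_gaussian(sub["log_rr"].to_numpy())
        pooled_rows.append(
            {
                "factor": factor,
                "k_obs": pe.k_obs,
                "model": pe.model,
                "rr_pp": pe.rr_pp,
                "tau2": pe.tau2,
                "ci_low": pe.ci_low,
                "ci_high": pe.ci_high,
                "percent_change": pe.percent_change,
                "significant": pe.significant,
                "q_total": pe.heterogeneity.q_total,
                "q_p_value": pe.heterogeneity.p_value,
            }
        )
    pooled_df = pd.DataFrame(pooled_rows)
    pooled_df.to_csv(out / "pooled_effects.csv", index=False)
    pooled_df[["factor", "rr_pp", "ci_low", "ci_high", "k_obs"]].to_csv(
        out / "forest_plot_data.csv", index=False
    )
    _stage("pool", t0, len(effects), len(pooled_df))

    # duration subgroups
    t0 = time.perf_counter()
    subgroup_rows = []
    subgroup_children = ss_subgroup.spawn(len(factors))
    for factor, child in zip(factors, subgroup_children):
        sub = effects.loc[effects["factor"] == factor]
        results, partition = moderators.subgroup_analysis(
            sub,
            edges=config.duration_edges,
            alpha=config.alpha,
            b=config.bootstrap_iterations,
            seed=np.random.default_rng(child),
            factor=factor,
        )
        for r in results:
            subgroup_rows.append(
                {
                    "factor": factor,
                    "group": r.group_label,
                    "n_studies": r.n_studies,
                    "n_obs": r.n_obs,
                    "included": r.included,
                    "rr_pp": r.pooled.rr_pp if r.pooled else None,
                    "ci_low": r.pooled.ci_low if r.pooled else None,
                    "ci_high": r.pooled.ci_high if r.pooled else None,
                    "percent_change": r.pooled.percent_change if r.pooled else None,
                    "q_between": partition.q_between if partition else None,
                    "p_between": partition.p_between if partition else None,
                }
            )
    subgroup_df = pd.DataFrame(subgroup_rows)
    subgroup_df.to_csv(out / "subgroups.csv", index=False)
    _stage("subgroups", t0, len(effects), len(subgroup_df))

    # meta-regression
    t0 = time.perf_counter()
    metareg_rows = []
    for factor in factors:
        sub = effects.loc[effects["factor"] == factor]
        for mod in config.meta_regression_moderators:
            try:
                r = moderators.meta_regress(sub, mod, alpha=config.alpha, factor=factor)
            except (ValueError, KeyError) as exc:
                log.info("meta-regression skipped (%s, %s): %s", factor, mod, exc)
                continue
            metareg_rows.append(dataclasses.asdict(r))
    metareg_df = pd.DataFrame(metareg_rows)
    metareg_df.to_csv(out / "meta_regression.csv", index=False)
    _stage("metareg", t0, len(effects), len(metareg_df))

    # publication bias
    t0 = time.perf_counter()
    bias_rows = [
        dataclasses.asdict(
            publication_bias.assess(
                effects.loc[effects["factor"] == f, "log_rr"].to_numpy(),
                effects.loc[effects["factor"] == f, "v"].to_numpy(),
                factor=f,
            )
        )
        for f in factors
    ]
    bias_df = pd.DataFrame(bias_rows)
    bias_df.to_csv(out / "publication_bias.csv", index=False)
    _stage("bias", t0, len(effects), len(bias_df))

    # variance partitioning on control-only rows
    t0 = time.perf_counter()
    forest_seeds = np.random.default_rng(ss_forest).integers(0, 2**31 - 1, 16)
    rf_r2 = {}
    for column_set in ("geoclimate", "quality", "both"):
        for time_filter in ("all", "le12", "gt12"):
            try:
                m = vp.build_matrix(harmonized, column_set, time_filter)
                rf_r2[f"{column_set}_{time_filter}"] = vp.rf_variance_explained(
                    m, n_trees=config.n_trees, seed=int(forest_seeds[len(rf_r2)])
                )
            except ValueError as exc:
                log.info("forest skipped (%s, %s): %s", column_set, time_filter, exc)
                rf_r2[f"{column_set}_{time_filter}"] = None

    m_both = vp.build_matrix(harmonized, "both", "all")
    importances = vp.rf_permutation_importance(
        m_both, n_trees=config.n_trees, n_perm=config.n_perm,
        seed=int(forest_seeds[10]), alpha=config.alpha,
    )
    pd.DataFrame([dataclasses.asdict(i) for i in importances]).to_csv(
        out / "rf_importance.csv", index=False
    )
    group_means = vp.group_mean_contribution(
        importances,
        config.column_groups,
        scale_to_r2=rf_r2["both_all"] if config.scale_importance_to_r2 else None,
    )

    composites = {
        name: vp.pc1_composite(m_both.X[cols], anchor=vp.PC1_ANCHORS.get(name))
        for name, cols in config.column_groups.items()
    }
    partition = vp.hierarchical_partition(m_both.y.to_numpy(), composites)
    pd.DataFrame([dataclasses.asdict(p) for p in partition]).to_csv(
        out / "hp_partition.csv", index=False
    )

    trait_rows = []
    for trait in ("aur", "aur_n", "n_conc"):
        try:
            r, p, n = vp.trait_correlation(harmonized, trait)
            trait_rows.append({"trait": trait, "r": r, "p_value": p, "n": n})
        except ValueError as exc:
            log.info("trait correlation skipped (%s): %s", trait, exc)
    trait_df = pd.DataFrame(trait_rows)
    trait_df.to_csv(out / "trait_correlations.csv", index=False)
    _stage("partition", t0, len(harmonized), len(trait_df))

    report = _jsonify(
        {
            "factors": {
                f: {
                    "k_obs": pe.k_obs,
                    "model": pe.model,
                    "rr_pp": pe.rr_pp,
                    "tau2": pe.tau2,
                    "ci_low": pe.ci_low,
                    "ci_high": pe.ci_high,
                    "percent_change": pe.percent_change,
                    "significant": pe.significant,
                    "q_total": pe.heterogeneity.q_total,
                    "q_p_value": pe.heterogeneity.p_value,
                    "gaussian_mu": gaussian_fits[f].mu,
                    "gaussian_sigma": gaussian_fits[f].sigma,
                    "fail_safe_n": bias_rows[i]["n_fs"],
                    "fail_safe_robust": bias_rows[i]["robust"],
                }
                for i, (f, pe) in enumerate(pooled_by_factor.items())
            },
            "rf_variance_explained": rf_r2,
            "group_mean_importance": group_means,
            "hierarchical_partition": {
                p.group: {
                    "independent_contribution": p.independent_contribution,
                    "total_model_r2": p.total_model_r2,
                }
                for p in partition
            },
            "trait_correlations": {row["trait"]: {"r": row["r"], "p_value": row["p_value"], "n": row["n"]} for row in trait_rows},
        }
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    manifest = _jsonify(
        {
            "seed": config.seed,
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
            "rows": {
                "observations_in": len(ingest.table) + len(ingest.quarantined),
                "quarantined": len(ingest.quarantined),
                "harmonized": len(harmonized),
                "dropped_harmonize": ingest_report["rows_in"] - ingest_report["rows_out"],
                "effects": len(effects),
                "excluded_control_only": effects_report["excluded_control_only"],
                "excluded_nonpositive_mean": effects_report["excluded_nonpositive_mean"],
                "pooled_factors": len(pooled_df),
            },
        }
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n")
    return report
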