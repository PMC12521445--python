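# Methods

This note documents the statistical model behind `rootmeta`, the choices
made where the methodology was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model and harmonization

The unit of analysis is one *observation*: percent mass loss of grassland
root litter after a given incubation, reported either as a
treatment/control pair (meta-analysis rows) or as a control group alone
(driver-importance rows).  Mass loss is stored on the percent scale
(0–100), durations in months, and every formula in the package is
documented against those units.

Literature tables need three repairs before effect sizes can be computed,
and all three are applied by `dataset.harmonize`:

* **Dispersion resolution.**  A value labelled `sd` passes through; `se`
  and `ambiguous` values are multiplied by √n (an unlabelled dispersion is
  read as a standard error — the conservative choice, since it inflates the
  resolved SD); a missing dispersion is imputed as one tenth of the group
  mean.  The `ambiguous` label is kept distinct from `se` in audit counts
  even though the arithmetic is identical.
* **Decay-constant conversion.**  Records reporting only an annual decay
  constant k are converted with the single negative-exponential (Olson)
  model, mass loss = (1 − e^(−k·t/12))·100.  The single-pool model is the
  universal convention in decomposition work; a double-exponential fit
  would require within-study time series that compiled tables rarely
  provide.  Converted rows are counted in the ingest report.
* **Inclusion filters.**  Rows lacking a duration, flagged as non-root
  substrate, or flagged as replacement sampling are dropped with a counted
  reason.  The substrate and sampling-design flags are ingestion columns —
  they cannot be inferred from the numbers.

Harmonization is idempotent: resolved SDs are written back as authoritative
`sd`-labelled values, so a second pass changes nothing.

## Effect sizes

lnRR = ln(X_t/X_c) with v = S_t²/(n_t X_t²) + S_c²/(n_c X_c²) and w = 1/v.
The variance is scale-free (percent vs fraction does not matter).  Two
degenerate cases are handled explicitly: observations with a nonpositive
mean are excluded (the ratio is undefined), and observations whose resolved
SDs are both zero get v floored at 1e-8 with a logged warning — a true zero
SD is a reporting artifact, and an infinite weight would otherwise swallow
the factor's analysis.

## Pooling and inference

Per factor: fixed-effects pooling (weights 1/v) → Cochran's Q against
χ²(k−1) at α = 0.05 → if significant, DerSimonian–Laird τ² and re-pooling
with weights 1/(v + τ²).  DL was chosen as the τ² estimator because it is
the classical method-of-moments default of the desktop meta-analysis
software generation this pipeline replaces; REML/ML are deliberately out of
scope.

Confidence intervals are **bias-corrected (BC, not BCa) bootstrap**
intervals.  The resampling unit is the individual observation (the analysis
weights and pools at observation level); a study-level cluster bootstrap is
available via `study_id=` for sensitivity analysis but is not the default.
Each resample re-runs the *entire* select-and-pool decision — Q test, τ²,
model choice — so the interval reflects model-selection uncertainty, not
just the variance of a fixed estimator.  The bias-correction constant is
z₀ = Φ⁻¹(#{θ* < θ̂}/B) (strictly-less-than tie convention), with the
proportion clamped to [1/(2B), 1 − 1/(2B)] in degenerate cases; endpoints
are bootstrap quantiles at Φ(2z₀ ± z_{0.975}).  With a perfectly symmetric
bootstrap distribution z₀ = 0 and the interval reduces to the percentile
interval (asserted in the tests).  The production default is B = 64,999
iterations; the test suite uses B = 1,999, which is ample for the
calibration checks it performs.

The per-factor Gaussian fit (`fit_gaussian`) is the ML normal fit of the
unweighted lnRR values, for frequency-distribution reporting only; it plays
no role in pooling.

## Moderators

Duration subgroups use half-open bins with configurable edges, default
{4, 6, 12, 18, 24} months (plus an under-4 and an open-ended ≥24 bin).
These edges are a reconstruction from the stage boundaries that recur in
the decomposition literature and must stay configurable.  A subgroup is
pooled only if it has ≥ 3 independent studies (distinct `study_id`s) or
≥ 10 observations.  Heterogeneity is decomposed as Q_total = Q_between +
ΣQ_within under common fixed-effects weights (exact identity, asserted to
1e-8), with Q_between referred to χ²(G−1).

Meta-regression fits lnRR on one moderator by weighted least squares in
three steps: fixed-effects fit → residual-Q method-of-moments τ²
(the design-matrix generalization of DL, τ² = max(0, (Q_E − (k−p))/
(tr W − tr((XᵀWX)⁻¹XᵀW²X)))) → final fit with weights 1/(v + τ²).
QM = (slope/se)² on χ²(1).  The implementation is verified against R's
`metafor` (method="DL") in the test suite.  Time-dependence screening is
exactly this regression with duration as the moderator.

## Publication bias

Rosenthal's fail-safe number, N_fs = max(0, (Σz)²/z_c² − k) with z_i =
lnRR_i/√v_i and one-tailed z_c = 1.645.  Rosenthal (not Orwin) is the
variant behind "fail-safe numbers" in the classical software lineage.  An
analysis is robust when N_fs strictly exceeds 5n + 10; ties count as not
robust.  A brute-force oracle (append null studies until the Stouffer
combined one-tailed p exceeds 0.05) agrees within ±1 by construction and is
asserted in the tests.

## Driver importance

Control-only observations feed a regression random forest.  The forest is a
bagged ensemble of CART trees (sklearn base learners) with *explicit*
bootstrap bookkeeping, because the pipeline needs out-of-bag quantities
sklearn does not expose: OOB pseudo-R² = 1 − MSE_oob/Var(y), and OOB
permutation importance (mean per-tree MSE increase when one predictor is
permuted among that tree's OOB rows, reported as % of Var(y)).
Significance comes from refitting the forest `n_perm` times with the
*response* permuted; p = (1 + #{null ≥ observed})/(n_perm + 1), never
exactly zero.  Defaults: 500 trees, ⌈p/3⌉ features per split, 100
permutations — all config-exposed.  Rows are keyed by `obs_id` and fitted
in canonical sorted order, so results are invariant to input row order.

Predictor sets follow the two driver groups — geoclimate {latitude,
longitude, elevation, MAT, MAP} and litter quality {AUR, C, N, P, AUR:N,
C:N} — with incubation duration always retained as a predictor (whether the
original analyses did so is unknowable; including it is the defensible
default since mass loss accumulates with time).  The temporal split puts
the 12-month boundary in the early (≤ 12) group.  Complete-case analysis
only: chemistry missingness is structural (AUR is only comparable across
studies using the AUR method), and imputing it would fabricate chemistry.

"Mean contribution" of a group is the arithmetic mean of its members'
permutation importances; how raw importances should be rescaled into the
contribution percentages reported in the literature is not standardized, so
a config switch (`scale_importance_to_r2`) optionally rescales importances
to sum to the model's explained variance before averaging.  The default is
the raw mean.

Hierarchical partitioning (Chevan–Sutherland) assigns each group the
average R² increment over all orderings in which it can enter a linear
model of the PC1 composites; for two groups IC_A = ½[R²(A) + R²(AB) −
R²(B)].  PC1 composites are computed on standardized columns with the sign
anchored so that the litter-N loading (quality) and the MAT loading
(geoclimate) are positive — without an anchor, PC signs are arbitrary and
runs would not be reproducible.  Contributions telescope to the full-model
R² (asserted to 1e-10 against an exhaustive all-subsets oracle).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular compiled dataset:

* ~69 sites in the two temperate bands (|lat| ∈ [25°, 55°]), MAT =
  28 − 0.6|lat| + noise, MAP log-normal with 400 mm median;
* litter chemistry: N% log-normal (median 0.8, clipped to [0.3, 2.5]),
  AUR% ~ Normal(25, 7) truncated above 5, C% ~ Normal(42, 3), P% log-normal
  (median 0.1); AUR:N and C:N computed, never drawn;
* decay: ln k = β₀ + β_N ln(N%) − β_AUR(AUR/25) + β_MAT(MAT/10) +
  β_MAP(MAP/1000) + u_site, with defaults β_N = 0.6, β_AUR = 0.8,
  β_MAT = 0.15, β_MAP = 0.2, σ_site = 0.25, and β₀ = 0.12 calibrated so the
  median one-year control mass loss is ≈ 40%.  This builds in the
  qualitative truths the analysis should recover: AUR and AUR:N slow
  decomposition, N accelerates it;
* treatment effects: per-study δ_s ~ Normal(lnRR_f, τ) with default true
  percent changes spanning +16.3% (P addition) to −27.8% (vegetated soil)
  across the 12 factors, and τ = 0.06 — "moderate" heterogeneity, I² ≈ 50%
  against the typical sampling variance v ≈ 2·CV²/n ≈ 0.004 implied by the
  default measurement CV of 0.10 and 3–6 replicates;
* reporting pathologies: dispersion blanked with probability 0.20 and
  mislabelled as an unlabelled SE with probability 0.10, so the harmonizer
  has real work to do.  Mass loss is clamped to (0.1, 99.9)% to keep log
  ratios defined.

Random streams are split hierarchically (sites / chemistry / studies /
noise / controls) from one seed; identical inputs give byte-identical CSVs.

What the generator does **not** emulate: real covariate joint
distributions, correlated moderators (e.g., chemistry responding to
climate), unbalanced factor sizes, digitization error, or selective
publication.  Passing recovery tests therefore demonstrates that the
*estimators* are correct and calibrated under the assumed model — not that
any particular field dataset satisfies those assumptions.

## Problem sizes and numerical choices

The default generated dataset is 8 studies × 12 observations per factor
(1,152 pairs) plus 2 control series per site (1,104 control rows) — the
scale of a large literature compilation in this area.  Recovery experiments
use 40 studies per factor with one observation each; calibration
experiments use 2,000 simulated factors (Q test) and 200 replicates
(bootstrap coverage at B = 1,999).  The acceptance script runs the full
pipeline at B = 64,999 and 500 trees with 60 response permutations.

Tie-breaks and degenerate inputs: z₀ ties counted strictly-less-than; all
bootstrap estimates identical → degenerate [x, x] interval with a warning;
τ² truncated at zero and set to zero (with a warning) when the weight sum
degenerates; p-values from permutation tests bounded below by 1/(n_perm+1);
zero-variance PCA columns and constant moderators are errors, not silent
drops.

## Known limitations

* The mixed-effects machinery is DL + inverse-variance weighting; it will
  not numerically match likelihood-based random-effects software.
* Whether the original bootstrap procedure resampled observations or
  studies is not documented in this literature; both are implemented,
  observation-level is the default.
* Meta-regression is single-moderator by design; no multi-moderator models.
* The hierarchical partitioning operates on linear PC1 composites; a
  nonlinear (forest-based) partition would generally attribute more
  variance but has no closed-form oracle to validate against.
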