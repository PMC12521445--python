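"""Synthetic multi-study root-decomposition datasets with known truth.

No compiled literature dataset is public for this problem, so the pipeline
is exercised on generated data whose ground truth is explicit.  The
generator emulates the statistical structure the analysis assumes:

* ~70 grassland sites in the two temperate bands, with MAT cooling away
  from the equator and log-normal MAP around a 400 mm median;
* root litter chemistry (N, AUR, C, P and derived AUR:N, C:N ratios) that
  drives decay through an Olson negative-exponential decay constant:
  recalcitrant (high-AUR) litter decomposes slowly, N-rich litter fast,
  warm and wet sites fast, with a log-normal site random effect;
* per-factor treatment effects: each study draws a true effect
  delta_s ~ Normal(lnRR_f, tau_f) and the treatment mean is the control
  mean scaled by e^delta_s;
* reporting noise: replicate counts, measurement CV, and the dispersion
  pathologies the harmonizer must fix (missing SDs, SE values with
  ambiguous labels).

Random streams are split hierarchically (sites / chemistry / studies /
noise) so that changing one count leaves the other components' draws
untouched, and identical (truth, counts, seed) yield byte-identical CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ALL_COLUMNS, CONTROL_ONLY, FACTORS

__all__ = [
    "TruthRecord",
    "SiteProfile",
    "default_truth",
    "generate_sites",
    "generate_chemistry",
    "control_mass_loss",
    "generate_meta_dataset",
    "write_observations_csv",
]

#: Default true percent change per factor.  Signs and magnitudes follow the
#: consensus directions for grassland root decomposition: nutrient addition,
#: warming, wetter conditions, elevated CO2 and grazing accelerate mass
#: loss; drought, living plant cover, mixing, away-from-home placement and
#: fauna exclusion slow it.
DEFAULT_PERCENT_CHANGE: dict[str, float] = {
    "n_addition": 4.49,
    "p_addition": 16.26,
    "warming": 9.80,
    "increased_precip": 5.95,
    "reduced_precip": -15.60,
    "elevated_co2": 14.03,
    "grazing": 7.51,
    "vegetated_soil": -27.84,
    "plant_richness": -4.99,
    "litter_richness": -5.93,
    "home_field": -4.34,
    "fauna_exclusion": -10.40,
}

#: Mass loss is clamped inside this open interval so log ratios stay defined.
MASS_LOSS_CLAMP = (0.1, 99.9)


@dataclass(frozen=True)
class SiteProfile:
    site_id: str
    latitude: float
    longitude: float
    elevation: float
    mat: float
    map: float


@dataclass
class TruthRecord:
    """Ground-truth parameters of one generated dataset.

    ``true_log_rr`` maps each factor to its true mean effect; ``tau`` is the
    between-study SD of true effects (shared across factors unless a
    per-factor mapping is given).  The decay model is

        ln k = beta0 + beta_n*ln(N%) - beta_aur*(AUR/25)
               + beta_mat*(MAT/10) + beta_map*(MAP/1000) + u_site,

    u_site ~ Normal(0, sigma_site), k per year.  ``measurement_cv`` is the
    replicate-level coefficient of variation; the two probabilities control
    how often dispersion fields are blanked or mislabelled.
    """

    true_log_rr: dict[str, float] = field(
        default_factory=lambda: {
            f: math.log(1.0 + pc / 100.0) for f, pc in DEFAULT_PERCENT_CHANGE.items()
        }
    )
    tau: float | dict[str, float] = 0.06
    beta0: float = 0.12
    beta_n: float = 0.6
    beta_aur: float = 0.8
    beta_mat: float = 0.15
    beta_map: float = 0.2
    sigma_site: float = 0.25
    measurement_cv: float = 0.10
    missing_sd_prob: float = 0.20
    ambiguous_label_prob: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        taus = self.tau.values() if isinstance(self.tau, dict) else [self.tau]
        if any(t < 0 for t in taus) or self.sigma_site < 0 or self.measurement_cv < 0:
            raise ValueError("SDs and CV must be nonnegative")
        for p in (self.missing_sd_prob, self.ambiguous_label_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def tau_for(self, factor: str) -> float:
        if isinstance(self.tau, dict):
            return float(self.tau[factor])
        return float(self.tau)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthRecord":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def default_truth() -> TruthRecord:
    """The default generation conditions (see DEFAULT_PERCENT_CHANGE)."""
    return TruthRecord()


def generate_sites(n_sites: int, seed) -> pd.DataFrame:
    """Draw grassland site profiles.

    Latitudes fall in the two temperate bands (|lat| in [25, 55]); MAT
    decreases with |latitude| (28 - 0.6|lat| plus noise); MAP is log-normal
    with a ~400 mm median.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    hemisphere = rng.choice([-1.0, 1.0], n_sites)
    lat = hemisphere * rng.uniform(25.0, 55.0, n_sites)
    lon = rng.uniform(-180.0, 180.0, n_sites)
    elevation = np.exp(rng.normal(math.log(800.0), 0.8, n_sites))
    mat = 28.0 - 0.6 * np.abs(lat) + rng.normal(0.0, 2.0, n_sites)
    map_ = np.exp(rng.normal(math.log(400.0), 0.45, n_sites))
    return pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(n_sites)],
            "latitude": np.round(lat, 3),
            "longitude": np.round(lon, 3),
            "elevation": np.round(elevation, 1),
            "mat": np.round(mat, 2),
            "map": np.round(map_, 1),
        }
    )


def generate_chemistry(n_litters: int, seed) -> pd.DataFrame:
    """Draw initial root litter chemistry.

    N% log-normal (median ~0.8, clipped to [0.3, 2.5]); AUR% normal
    (25 +/- 7, truncated above 5); C% ~ 42 +/- 3; P% log-normal (median
    ~0.1).  AUR:N and C:N are computed from the components, never drawn.
    """
    if n_litters < 1:
        raise ValueError("n_litters must be >= 1")
    rng = np.random.default_rng(seed)
    n_conc = np.clip(np.exp(rng.normal(math.log(0.8), 0.40, n_litters)), 0.3, 2.5)
    aur = rng.normal(25.0, 7.0, n_litters)
    while np.any(aur <= 5.0):  # truncation by redraw
        bad = aur <= 5.0
        aur[bad] = rng.normal(25.0, 7.0, int(bad.sum()))
    c = rng.normal(42.0, 3.0, n_litters)
    p_conc = np.exp(rng.normal(math.log(0.1), 0.35, n_litters))
    df = pd.DataFrame(
        {
            "aur": np.round(aur, 2),
            "c": np.round(c, 2),
            "n_conc": np.round(n_conc, 3),
            "p_conc": np.round(p_conc, 4),
        }
    )
    df["aur_n"] = np.round(df["aur"] / df["n_conc"], 2)
    df["c_n"] = np.round(df["c"] / df["n_conc"], 2)
    return df


def _log_k(truth: TruthRecord, site, chem, u_site: float) -> float:
    return (
        truth.beta0
        + truth.beta_n * math.log(chem["n_conc"])
        - truth.beta_aur * (chem["aur"] / 25.0)
        + truth.beta_mat * (site["mat"] / 10.0)
        + truth.beta_map * (site["map"] / 1000.0)
        + u_site
    )


def control_mass_loss(
    site,
    chem,
    duration_months: float,
    noise_cv: float = 0.0,
    seed=None,
    truth: TruthRecord | None = None,
    u_site: float | None = None,
) -> float:
    """Expected control mass loss (%) for one site/litter/duration.

    Deterministic given ``u_site``; if ``u_site`` is None the site effect is
    drawn from Normal(0, sigma_site).  ``noise_cv`` applies multiplicative
    log-normal measurement noise.  Clamped to (0.1, 99.9).
    """
    if duration_months <= 0:
        raise ValueError("duration must be positive")
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    if u_site is None:
        u_site = float(rng.normal(0.0, truth.sigma_site))
    k = math.exp(_log_k(truth, site, chem, u_site))
    loss = (1.0 - math.exp(-k * duration_months / 12.0)) * 100.0
    if noise_cv > 0:
        loss *= float(np.exp(rng.normal(0.0, noise_cv)))
    return float(np.clip(loss, *MASS_LOSS_CLAMP))


#: Sampling time points (months) for paired studies and control series.
PAIRED_DURATION_POOL = (2.0, 3.0, 4.0, 5.0, 6.0, 9.0, 12.0, 15.0, 18.0, 24.0, 30.0, 36.0)
CONTROL_DURATIONS = (3.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0, 36.0)


def generate_meta_dataset(
    truth: TruthRecord | None = None,
    n_studies_per_factor: int = 8,
    obs_per_study: int = 12,
    seed: int | None = None,
    n_sites: int = 69,
    control_series_per_site: int = 2,
) -> pd.DataFrame:
    """Generate a full observation table in the ingestion schema.

    Each factor gets ``n_studies_per_factor`` studies; a study sits at one
    site with one litter type, draws a true effect delta_s ~ Normal(lnRR_f,
    tau_f), and reports ``obs_per_study`` time points (non-replacement
    sampling: one litterbag cohort followed through time).  Control-only
    series (``control_series_per_site`` per site) feed the driver-importance
    stage.  Fully deterministic under (truth, counts, seed).
    """
    truth = truth or default_truth()
    if n_studies_per_factor < 1 or obs_per_study < 1:
        raise ValueError("counts must be >= 1")
    root = np.random.SeedSequence(seed if seed is not None else truth.seed)
    ss_sites, ss_chem, ss_studies, ss_noise, ss_control, ss_control_chem = root.spawn(6)

    sites = generate_sites(n_sites, ss_sites)
    chems = generate_chemistry(n_studies_per_factor * len(FACTORS), ss_chem)
    n_control_chem = n_sites * control_series_per_site
    control_chems = (
        generate_chemistry(n_control_chem, ss_control_chem) if n_control_chem else None
    )
    site_rng = np.random.default_rng(ss_sites.spawn(1)[0])
    u_sites = site_rng.normal(0.0, truth.sigma_site, n_sites)

    study_rng = np.random.default_rng(ss_studies)
    noise_rng = np.random.default_rng(ss_noise)
    rows: list[dict] = []
    chem_cursor = 0
    obs_counter = 0
    study_counter = 0

    def _report_group(mean: float, n_reps: int) -> dict:
        """Observed mean, dispersion field and label for one group."""
        obs_mean = float(
            np.clip(mean * math.exp(noise_rng.normal(0.0, truth.measurement_cv / math.sqrt(n_reps))),
                    *MASS_LOSS_CLAMP)
        )
        sd = truth.measurement_cv * obs_mean
        u = noise_rng.uniform()
        if u < truth.missing_sd_prob:
            return {"mean": obs_mean, "disp": "", "label": "missing", "n": n_reps}
        if u < truth.missing_sd_prob + truth.ambiguous_label_prob:
            # the study printed a standard error but did not say so
            return {
                "mean": obs_mean,
                "disp": round(sd / math.sqrt(n_reps), 6),
                "label": "ambiguous",
                "n": n_reps,
            }
        return {"mean": obs_mean, "disp": round(sd, 6), "label": "sd", "n": n_reps}

    def _row_base(site, chem, duration: float) -> dict:
        return {
            "site_id": site["site_id"],
            "duration_months": duration,
            "latitude": site["latitude"],
            "longitude": site["longitude"],
            "elevation": site["elevation"],
            "mat": site["mat"],
            "map": site["map"],
            **{col: chem[col] for col in ("aur", "c", "n_conc", "p_conc", "aur_n", "c_n")},
            "mesh_mm": 1.0,
            "depth_cm": 10.0,
            "diameter_mm": 1.0,
            "root_substrate": "true",
            "non_replacement": "true",
        }

    for factor in FACTORS:
        delta = study_rng.normal(truth.true_log_rr[factor], truth.tau_for(factor),
                                 n_studies_per_factor)
        site_idx = study_rng.integers(0, n_sites, n_studies_per_factor)
        for s in range(n_studies_per_factor):
            site = sites.iloc[int(site_idx[s])]
            chem = chems.iloc[chem_cursor]
            chem_cursor += 1
            study_id = f"study{study_counter:04d}"
            study_counter += 1
            n_reps = int(study_rng.integers(3, 7))
            durations = np.sort(
                study_rng.choice(PAIRED_DURATION_POOL, size=obs_per_study, replace=False)
                if obs_per_study <= len(PAIRED_DURATION_POOL)
                else study_rng.choice(PAIRED_DURATION_POOL, size=obs_per_study)
            )
            for t in durations:
                true_control = control_mass_loss(
                    site, chem, float(t), noise_cv=0.0, truth=truth,
                    u_site=float(u_sites[int(site_idx[s])]),
                )
                true_treatment = float(np.clip(true_control * math.exp(delta[s]),
                                               *MASS_LOSS_CLAMP))
                cg = _report_group(true_control, n_reps)
                tg = _report_group(true_treatment, n_reps)
                rows.append(
                    {
                        "obs_id": f"obs{obs_counter:05d}",
                        "study_id": study_id,
                        "factor": factor,
                        **_row_base(site, chem, float(t)),
                        "control_mean": round(cg["mean"], 4),
                        "control_disp": cg["disp"],
                        "control_disp_label": cg["label"],
                        "control_n": cg["n"],
                        "treatment_mean": round(tg["mean"], 4),
                        "treatment_disp": tg["disp"],
                        "treatment_disp_label": tg["label"],
                        "treatment_n": tg["n"],
                    }
                )
                obs_counter += 1

    control_rng = np.random.default_rng(ss_control)
    control_chem_cursor = 0
    for i in range(n_sites):
        site = sites.iloc[i]
        for _series in range(control_series_per_site):
            chem = control_chems.iloc[control_chem_cursor]
            control_chem_cursor += 1
            study_id = f"study{study_counter:04d}"
            study_counter += 1
            n_reps = int(control_rng.integers(3, 7))
            for t in CONTROL_DURATIONS:
                loss = control_mass_loss(
                    site, chem, t, noise_cv=truth.measurement_cv / math.sqrt(n_reps),
                    seed=control_rng, truth=truth, u_site=float(u_sites[i]),
                )
                sd = truth.measurement_cv * loss
                rows.append(
                    {
                        "obs_id": f"obs{obs_counter:05d}",
                        "study_id": study_id,
                        "factor": CONTROL_ONLY,
                        **_row_base(site, chem, t),
                        "control_mean": round(loss, 4),
                        "control_disp": round(sd, 6),
                        "control_disp_label": "sd",
                        "control_n": n_reps,
                        "treatment_mean": "",
                        "treatment_disp": "",
                        "treatment_disp_label": "",
                        "treatment_n": "",
                    }
                )
                obs_counter += 1

    df = pd.DataFrame(rows)
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[list(ALL_COLUMNS)]


def write_observations_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table in the documented CSV dialect."""
    df.to_csv(path, index=False)
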