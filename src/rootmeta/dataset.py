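"""Observation data model, CSV ingestion and harmonization.

The unit of analysis is one *observation*: the mass loss (% of initial dry
mass) of grassland root litter after a given field incubation, reported for a
treatment/control pair (meta-analysis rows) or for a control group alone
(rows feeding the driver-importance stage).  Literature-extracted tables are
messy in predictable ways, and this module encodes the harmonization rules
used throughout the pipeline:

* dispersion reported without a label is treated as a standard error and
  converted to an SD (the conservative reading);
* dispersion missing entirely is imputed as one tenth of the group mean;
* records reporting only a decay constant ``k`` (per year) are converted to
  mass loss with the single negative-exponential (Olson) model;
* rows violating inclusion rules (non-root substrate, replacement sampling,
  missing duration) are dropped with a counted reason, never silently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "CONTROL_ONLY",
    "SCHEMA_VERSION",
    "GroupSummary",
    "Moderators",
    "Observation",
    "DecayRecord",
    "IngestResult",
    "SchemaError",
    "read_observations",
    "resolve_sd",
    "mass_loss_from_k",
    "harmonize",
]

SCHEMA_VERSION = "1"

#: The twelve experimental factors contrasted against controls.
FACTORS = (
    "n_addition",
    "p_addition",
    "warming",
    "increased_precip",
    "reduced_precip",
    "elevated_co2",
    "grazing",
    "vegetated_soil",
    "plant_richness",
    "litter_richness",
    "home_field",
    "fauna_exclusion",
)

#: Sentinel factor label for rows with no treatment group.
CONTROL_ONLY = "control_only"

DISPERSION_LABELS = ("sd", "se", "ambiguous", "missing")

#: Columns that must be present in the CSV header.
MANDATORY_COLUMNS = (
    "obs_id",
    "study_id",
    "site_id",
    "factor",
    "duration_months",
    "control_mean",
    "control_n",
)

#: Optional columns, in canonical order (all may be empty per row).
OPTIONAL_COLUMNS = (
    "control_disp",
    "control_disp_label",
    "control_k",
    "treatment_mean",
    "treatment_disp",
    "treatment_disp_label",
    "treatment_n",
    "treatment_k",
    "latitude",
    "longitude",
    "elevation",
    "mat",
    "map",
    "aur",
    "c",
    "n_conc",
    "p_conc",
    "aur_n",
    "c_n",
    "mesh_mm",
    "depth_cm",
    "diameter_mm",
    "root_substrate",
    "non_replacement",
)

ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

#: Continuous moderator columns carried through to effect sizes.
MODERATOR_COLUMNS = (
    "duration_months",
    "latitude",
    "longitude",
    "elevation",
    "mat",
    "map",
    "aur",
    "c",
    "n_conc",
    "p_conc",
    "aur_n",
    "c_n",
    "mesh_mm",
    "depth_cm",
    "diameter_mm",
)


class SchemaError(ValueError):
    """The CSV header does not match the documented observation schema."""


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group (treatment or control).

    ``mean_mass_loss`` is the percent of initial mass lost, in [0, 100];
    ``dispersion_label`` says how ``dispersion_value`` is to be read.
    """

    mean_mass_loss: float
    dispersion_value: float | None
    dispersion_label: str
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_mass_loss <= 100.0:
            raise ValueError(
                f"mean_mass_loss must be in [0, 100], got {self.mean_mass_loss}"
            )
        if self.n < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n}")
        if self.dispersion_label not in DISPERSION_LABELS:
            raise ValueError(f"unknown dispersion label {self.dispersion_label!r}")
        if self.dispersion_value is not None and self.dispersion_value < 0:
            raise ValueError("dispersion_value must be nonnegative")


@dataclass(frozen=True)
class Moderators:
    """Continuous moderators attached to one observation.

    Everything except incubation duration may be missing (None).
    Units: months, degrees, m, degC, mm/yr, % of dry mass, mm, cm.
    """

    duration_months: float
    latitude: float | None = None
    longitude: float | None = None
    elevation: float | None = None
    mat: float | None = None
    map: float | None = None
    aur: float | None = None
    c: float | None = None
    n_conc: float | None = None
    p_conc: float | None = None
    aur_n: float | None = None
    c_n: float | None = None
    mesh_mm: float | None = None
    depth_cm: float | None = None
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.duration_months > 0:
            raise ValueError("duration_months must be positive")
        if self.map is not None and self.map < 0:
            raise ValueError("map must be nonnegative")
        for name in ("aur_n", "c_n"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class Observation:
    """One treatment/control pair, or a control-only record."""

    obs_id: str
    study_id: str
    site_id: str
    factor: str
    control: GroupSummary
    moderators: Moderators
    treatment: GroupSummary | None = None

    def __post_init__(self) -> None:
        if self.factor not in FACTORS and self.factor != CONTROL_ONLY:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.factor == CONTROL_ONLY and self.treatment is not None:
            raise ValueError("control-only observations carry no treatment group")


@dataclass(frozen=True)
class DecayRecord:
    """A decay constant (per year) observed over a given duration."""

    k_value: float
    duration_months: float

    def __post_init__(self) -> None:
        if self.k_value < 0:
            raise ValueError("decay constant must be nonnegative")
        if not self.duration_months > 0:
            raise ValueError("duration must be positive")


@dataclass
class IngestResult:
    """Parsed table plus per-row validation issues.

    ``table`` holds the rows that passed validation (original order);
    ``quarantined`` the rows that failed, with ``issues`` giving one
    (row_index, message) pair per problem.
    """

    table: pd.DataFrame
    quarantined: pd.DataFrame
    issues: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.table)


def resolve_sd(g: GroupSummary) -> float:
    """Resolve a group's dispersion field to a standard deviation.

    ``sd`` passes through; ``se`` and ``ambiguous`` are scaled by sqrt(n)
    (an unlabelled dispersion is assumed to be a standard error); ``missing``
    is imputed as mean/10.
    """
    if g.dispersion_label == "sd":
        if g.dispersion_value is None:
            raise ValueError("label 'sd' requires a dispersion value")
        return float(g.dispersion_value)
    if g.dispersion_label in ("se", "ambiguous"):
        if g.dispersion_value is None:
            raise ValueError(f"label {g.dispersion_label!r} requires a value")
        return float(g.dispersion_value) * math.sqrt(g.n)
    # missing -> mean/10 imputation
    return g.mean_mass_loss / 10.0


def mass_loss_from_k(rec: DecayRecord) -> float:
    """Convert a decay constant to percent mass loss.

    Uses the single negative-exponential decay model
    ``M_t = M_0 * exp(-k t)`` with ``k`` per year and duration in months,
    so mass loss = (1 - exp(-k * t/12)) * 100.
    """
    t_years = rec.duration_months / 12.0
    return (1.0 - math.exp(-rec.k_value * t_years)) * 100.0


def read_observations(path: str | Path, schema_version: str = SCHEMA_VERSION) -> IngestResult:
    """Read and validate an ``observations.csv`` file.

    Raises :class:`SchemaError` if a mandatory column is missing or the
    schema version is not recognised.  Row-level problems (non-numeric
    mandatory cell, out-of-range mass loss, unknown factor or dispersion
    label) quarantine the row and are recorded in ``issues``; valid rows are
    returned in their original order.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""
    return _validate_rows(raw)


NUMERIC_COLUMNS = (
    "duration_months",
    "control_mean",
    "control_disp",
    "control_n",
    "control_k",
    "treatment_mean",
    "treatment_disp",
    "treatment_n",
    "treatment_k",
    "latitude",
    "longitude",
    "elevation",
    "mat",
    "map",
    "aur",
    "c",
    "n_conc",
    "p_conc",
    "aur_n",
    "c_n",
    "mesh_mm",
    "depth_cm",
    "diameter_mm",
)

BOOL_COLUMNS = ("root_substrate", "non_replacement")


def _to_float(cell: str) -> float:
    """Empty cell -> NaN; non-numeric -> ValueError."""
    s = cell.strip()
    if s == "":
        return math.nan
    return float(s)


def _to_bool(cell: str) -> bool | float:
    s = cell.strip().lower()
    if s == "":
        return math.nan
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def _validate_rows(raw: pd.DataFrame) -> IngestResult:
    issues: list[tuple[int, str]] = []
    records: list[dict] = []
    bad_index: list[int] = []
    for i, row in raw.iterrows():
        rec: dict = {
            "obs_id": row["obs_id"].strip(),
            "study_id": row["study_id"].strip(),
            "site_id": row["site_id"].strip(),
            "factor": row["factor"].strip(),
        }
        row_issues: list[str] = []
        for col in NUMERIC_COLUMNS:
            try:
                rec[col] = _to_float(row[col])
            except ValueError:
                row_issues.append(f"non-numeric value in column '{col}': {row[col]!r}")
                rec[col] = math.nan
        for col in BOOL_COLUMNS:
            try:
                rec[col] = _to_bool(row[col])
            except ValueError as exc:
                row_issues.append(f"column '{col}': {exc}")
                rec[col] = math.nan
        for col in ("control_disp_label", "treatment_disp_label"):
            lab = row[col].strip().lower() or "missing"
            if lab not in DISPERSION_LABELS:
                row_issues.append(f"unknown dispersion label {lab!r} in '{col}'")
            rec[col] = lab
        if rec["factor"] not in FACTORS and rec["factor"] != CONTROL_ONLY:
            row_issues.append(f"unknown factor {rec['factor']!r}")
        for col in ("control_mean", "treatment_mean"):
            v = rec.get(col, math.nan)
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                row_issues.append(f"{col}={v} outside [0, 100]")
        for col in ("control_n", "treatment_n"):
            v = rec.get(col, math.nan)
            if not math.isnan(v) and v < 1:
                row_issues.append(f"{col}={v} below 1")
        for col in ("control_disp", "treatment_disp"):
            v = rec.get(col, math.nan)
            if not math.isnan(v) and v < 0:
                row_issues.append(f"{col}={v} negative")
        if row_issues:
            bad_index.append(i)
            issues.extend((i, msg) for msg in row_issues)
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    bad_mask = table.index.isin(bad_index)
    return IngestResult(
        table=table.loc[~bad_mask].reset_index(drop=True),
        quarantined=table.loc[bad_mask].reset_index(drop=True),
        issues=issues,
    )


def _resolve_sd_frame(df: pd.DataFrame, prefix: str) -> tuple[pd.Series, pd.Series]:
    """Vectorised resolve_sd for one group; returns (sd, was_imputed_or_converted)."""
    mean = df[f"{prefix}_mean"]
    disp = df[f"{prefix}_disp"]
    label = df[f"{prefix}_disp_label"]
    n = df[f"{prefix}_n"]
    # a labelled value that is actually absent degrades to 'missing'
    label = label.where(~(disp.isna() & label.isin(["sd", "se", "ambiguous"])), "missing")
    sd = pd.Series(np.nan, index=df.index, dtype=float)
    sd[label == "sd"] = disp[label == "sd"]
    se_like = label.isin(["se", "ambiguous"])
    sd[se_like] = disp[se_like] * np.sqrt(n[se_like])
    missing = label == "missing"
    sd[missing] = mean[missing] / 10.0
    return sd, label != "sd"


def harmonize(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the harmonization rules to a validated observation table.

    Returns ``(harmonized, report)``:

    * decay-constant-only records get mass loss filled from ``k``;
    * both groups get a resolved ``*_sd`` column (SE->SD conversion,
      mean/10 imputation);
    * rows with no duration, a non-root substrate flag, or a replacement
      sampling flag are dropped (counted by reason in the report).

    The operation is idempotent: harmonizing an already harmonized table is
    a no-op apart from the report counts.
    """
    df = table.copy()
    report: dict[str, int] = {
        "rows_in": len(df),
        "dropped_no_duration": 0,
        "dropped_non_root": 0,
        "dropped_replacement_sampling": 0,
        "k_converted_control": 0,
        "k_converted_treatment": 0,
        "sd_resolved_control": 0,
        "sd_resolved_treatment": 0,
    }

    keep = pd.Series(True, index=df.index)
    no_dur = df["duration_months"].isna() | (df["duration_months"] <= 0)
    report["dropped_no_duration"] = int(no_dur.sum())
    keep &= ~no_dur
    if "root_substrate" in df.columns:
        non_root = df["root_substrate"] == False  # noqa: E712 (NaN must pass)
        report["dropped_non_root"] = int((non_root & keep).sum())
        keep &= ~non_root
    if "non_replacement" in df.columns:
        repl = df["non_replacement"] == False  # noqa: E712
        report["dropped_replacement_sampling"] = int((repl & keep).sum())
        keep &= ~repl
    df = df.loc[keep].reset_index(drop=True)

    # k -> mass loss where the mean is absent
    t_years = df["duration_months"] / 12.0
    for prefix in ("control", "treatment"):
        kcol, mcol = f"{prefix}_k", f"{prefix}_mean"
        fill = df[mcol].isna() & df[kcol].notna() & (df[kcol] >= 0)
        df.loc[fill, mcol] = (1.0 - np.exp(-df.loc[fill, kcol] * t_years[fill])) * 100.0
        report[f"k_converted_{prefix}"] = int(fill.sum())

    # resolved SDs (skip the treatment columns of control-only rows)
    sd_c, changed_c = _resolve_sd_frame(df, "control")
    df["control_sd"] = sd_c
    report["sd_resolved_control"] = int((changed_c & df["control_mean"].notna()).sum())
    has_t = df["treatment_mean"].notna()
    sd_t, changed_t = _resolve_sd_frame(df, "treatment")
    df["treatment_sd"] = sd_t.where(has_t)
    report["sd_resolved_treatment"] = int((changed_t & has_t).sum())
    # once resolved, the dispersion fields are authoritative SDs
    df["control_disp"] = df["control_sd"]
    df["control_disp_label"] = "sd"
    df.loc[has_t, "treatment_disp"] = df.loc[has_t, "treatment_sd"]
    df.loc[has_t, "treatment_disp_label"] = "sd"
    report["rows_out"] = len(df)
    return df, report


def write_ingest_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def iter_observations(harmonized: pd.DataFrame) -> Iterable[Observation]:
    """Yield typed :class:`Observation` records from a harmonized table."""
    for _, row in harmonized.iterrows():
        control = GroupSummary(
            mean_mass_loss=float(row["control_mean"]),
            dispersion_value=None if pd.isna(row["control_sd"]) else float(row["control_sd"]),
            dispersion_label="sd" if not pd.isna(row["control_sd"]) else "missing",
            n=int(row["control_n"]),
        )
        treatment = None
        if not pd.isna(row.get("treatment_mean", np.nan)):
            treatment = GroupSummary(
                mean_mass_loss=float(row["treatment_mean"]),
                dispersion_value=None
                if pd.isna(row["treatment_sd"])
                else float(row["treatment_sd"]),
                dispersion_label="sd" if not pd.isna(row["treatment_sd"]) else "missing",
                n=int(row["treatment_n"]),
            )
        mods = Moderators(
            **{
                name: (None if pd.isna(row[name]) else float(row[name]))
                for name in MODERATOR_COLUMNS
                if name != "duration_months"
            },
            duration_months=float(row["duration_months"]),
        )
        yield Observation(
            obs_id=str(row["obs_id"]),
            study_id=str(row["study_id"]),
            site_id=str(row["site_id"]),
            factor=str(row["factor"]),
            control=control,
            treatment=treatment,
            moderators=mods,
        )
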