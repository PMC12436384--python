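"""Event-record datasets (NONMEM-style CSV), BLQ handling and covariate
summaries.

A dataset is a flat table of dosing rows (EVID=1) and observation rows
(EVID=0) with per-row covariates, wrapped in :class:`AnalysisDataset`.
Concentrations below the assay's lower limit of quantification (LLOQ) are
flagged BLQ; the M1 convention simply discards them before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

#: required columns of the event-record CSV dialect
COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "CMT", "BLQ",
    "BW", "AGE", "SEX", "BMI", "BSA", "STATE", "STUDY",
]

STUDIES = ("phase1_part1", "phase1_part2", "phase1_part3", "phase3")

#: default assay lower limit of quantification, pg/mL; at this LLOQ the
#: synthetic full-study design leaves ~1% of observations BLQ
DEFAULT_LLOQ = 2.0

SEX_MALE, SEX_FEMALE = 0, 1
STATE_HV, STATE_PATIENT = 0, 1


class SchemaError(ValueError):
    """The CSV does not have the expected columns/types."""


class ValidationError(ValueError):
    """The event records violate a dataset invariant."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates of one subject."""

    bw: float           # kg
    age: float          # years
    sex: int            # 0 = male, 1 = female
    bmi: float          # kg/m^2
    bsa: float          # m^2
    state: int          # 0 = healthy volunteer, 1 = patient
    study: str

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"bw must be positive, got {self.bw!r}")
        if self.sex not in (SEX_MALE, SEX_FEMALE):
            raise ValueError(f"sex must be 0 (male) or 1 (female), got {self.sex!r}")
        if self.state not in (STATE_HV, STATE_PATIENT):
            raise ValueError(f"state must be 0 (HV) or 1 (patient), got {self.state!r}")
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}")

    @property
    def is_hv(self) -> bool:
        return self.state == STATE_HV


@dataclass
class AnalysisDataset:
    """Event records plus the assay LLOQ.

    ``records`` holds one row per event with the columns in
    :data:`COLUMNS`; covariates are constant within subject.
    """

    records: pd.DataFrame
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        validate_records(self.records)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.records["ID"].nunique())

    @property
    def n_observations(self) -> int:
        """Quantifiable observation rows (EVID=0, MDV=0)."""
        r = self.records
        return int(((r["EVID"] == 0) & (r["MDV"] == 0)).sum())

    def observations(self) -> pd.DataFrame:
        r = self.records
        return r[(r["EVID"] == 0) & (r["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    def covariates(self) -> pd.DataFrame:
        """One row per subject, indexed by ID."""
        cols = ["BW", "AGE", "SEX", "BMI", "BSA", "STATE", "STUDY"]
        return self.records.groupby("ID", sort=False)[cols].first()

    def subject_covariates(self, subject_id) -> SubjectCovariates:
        row = self.covariates().loc[subject_id]
        return SubjectCovariates(
            bw=float(row["BW"]), age=float(row["AGE"]), sex=int(row["SEX"]),
            bmi=float(row["BMI"]), bsa=float(row["BSA"]), state=int(row["STATE"]),
            study=str(row["STUDY"]),
        )


def validate_records(df: pd.DataFrame) -> None:
    """Raise on schema or invariant violations."""
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.empty:
        raise ValidationError("dataset has no rows")
    if not df["EVID"].isin([0, 1]).all():
        raise ValidationError("EVID must be 0 (observation) or 1 (dose)")
    doses = df[df["EVID"] == 1]
    if (doses["AMT"] <= 0).any():
        raise ValidationError("dose rows (EVID=1) must have AMT > 0")
    if (doses["MDV"] != 1).any():
        raise ValidationError("dose rows (EVID=1) must have MDV = 1")
    obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)]
    if obs["DV"].isna().any():
        raise ValidationError("observation rows (MDV=0) must have a numeric DV")
    if not np.isfinite(obs["DV"].to_numpy(dtype=float)).all():
        raise ValidationError("observation DV values must be finite")
    bad_dv = obs[(obs["DV"] < 0) & (~obs["BLQ"].astype(bool))]
    if len(bad_dv):
        raise ValidationError("negative DV only allowed on BLQ-flagged rows")
    cov_cols = ["BW", "AGE", "SEX", "BMI", "BSA", "STATE"]
    if df[cov_cols].isna().any().any():
        missing = [c for c in cov_cols if df[c].isna().any()]
        raise ValidationError(f"missing covariate values in columns {missing}")
    if not df["STUDY"].isin(STUDIES).all():
        bad = sorted(set(df["STUDY"]) - set(STUDIES))
        raise ValidationError(f"unknown STUDY codes {bad}")
    # state must agree with study phase
    is_p1 = df["STUDY"].str.startswith("phase1")
    if ((df["STATE"] == STATE_HV) != is_p1).any():
        raise ValidationError("STATE must be HV exactly for phase 1 studies")
    for sid, g in df.groupby("ID", sort=False):
        if np.any(np.diff(g["TIME"].to_numpy(dtype=float)) < 0):
            raise ValidationError(f"times not non-decreasing for subject {sid}")
        if (g["EVID"] == 1).sum() < 1:
            raise ValidationError(f"subject {sid} has no dose record")
        if ((g["EVID"] == 0) & (g["MDV"] == 0)).sum() < 1:
            raise ValidationError(f"subject {sid} has no quantifiable observation")
        cov = g[cov_cols + ["STUDY"]]
        if (cov.nunique() > 1).any():
            raise ValidationError(f"covariates vary within subject {sid}")


def flag_blq(df: pd.DataFrame, lloq: float) -> pd.DataFrame:
    """Set BLQ=1 on quantifiable observation rows with DV below the LLOQ."""
    out = df.copy()
    is_obs = (out["EVID"] == 0) & (out["MDV"] == 0)
    out["BLQ"] = (is_obs & (out["DV"] < lloq)).astype(int)
    return out


def read_dataset(path, lloq: float = DEFAULT_LLOQ) -> AnalysisDataset:
    """Read an event-record CSV and flag BLQ observations.

    Missing DV is accepted (as blank or ``NA``) only on MDV=1 rows.
    """
    df = pd.read_csv(path, na_values=["NA", "."])
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    numeric = [c for c in COLUMNS if c != "STUDY"]
    try:
        df[numeric] = df[numeric].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric value in numeric column: {exc}") from exc
    df = flag_blq(df, lloq)
    ds = AnalysisDataset(records=df[COLUMNS].reset_index(drop=True), lloq=lloq)
    return ds


def write_dataset(ds: AnalysisDataset, path) -> None:
    """Write the event records back to CSV (inverse of :func:`read_dataset`)."""
    ds.records[COLUMNS].to_csv(path, index=False)


class BlqFilterResult(NamedTuple):
    dataset: AnalysisDataset
    n_removed: int
    fraction_removed: float


def apply_blq_m1(ds: AnalysisDataset) -> BlqFilterResult:
    """Discard BLQ observation rows (the M1 convention).

    Dose rows and missing-DV rows are untouched.  Returns the filtered
    dataset together with the fraction of quantifiable observations
    removed.
    """
    r = ds.records
    is_blq_obs = (r["EVID"] == 0) & (r["MDV"] == 0) & (r["BLQ"].astype(bool))
    n_obs = ds.n_observations
    n_removed = int(is_blq_obs.sum())
    if n_obs and n_removed == n_obs:
        warnings.warn("all observations are BLQ; filtered dataset is empty")
    kept = r[~is_blq_obs]
    remaining = kept[(kept["EVID"] == 0) & (kept["MDV"] == 0)]["ID"].unique()
    orphans = set(kept["ID"].unique()) - set(remaining)
    if orphans:
        warnings.warn(
            f"{len(orphans)} subject(s) lost all observations to BLQ filtering "
            "and were dropped"
        )
        kept = kept[~kept["ID"].isin(orphans)]
    out = AnalysisDataset(records=kept.reset_index(drop=True), lloq=ds.lloq)
    fraction = n_removed / n_obs if n_obs else 0.0
    return BlqFilterResult(out, n_removed, fraction)


def _fmt(x: float) -> str:
    return f"{x:g}"


def summarize_covariates(ds: AnalysisDataset) -> pd.DataFrame:
    """Median (min-max) of AGE/BW/BMI/BSA and sex counts, per study and total.

    Phase 1 parts are pooled into a single ``phase1`` column, mirroring the
    usual baseline-characteristics table.
    """
    cov = ds.covariates().copy()
    cov["GROUP"] = np.where(
        cov["STUDY"].str.startswith("phase1"), "phase1", "phase3"
    )
    groups = [g for g in ("phase1", "phase3") if (cov["GROUP"] == g).any()]
    rows = {}
    for name in ("AGE", "BW", "BMI", "BSA"):
        row = {}
        for g in groups:
            x = cov.loc[cov["GROUP"] == g, name].to_numpy(dtype=float)
            row[g] = f"{_fmt(np.median(x))} ({_fmt(x.min())}-{_fmt(x.max())})"
        x = cov[name].to_numpy(dtype=float)
        row["total"] = f"{_fmt(np.median(x))} ({_fmt(x.min())}-{_fmt(x.max())})"
        rows[name] = row
    row = {}
    for g in groups + ["total"]:
        sub = cov if g == "total" else cov[cov["GROUP"] == g]
        male = int((sub["SEX"] == SEX_MALE).sum())
        female = int((sub["SEX"] == SEX_FEMALE).sum())
        row[g] = f"{male}/{female}"
    rows["SEX (M/F)"] = row
    out = pd.DataFrame(rows).T
    out.index.name = "covariate"
    return out
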