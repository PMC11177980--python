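"""Cohort container, CSV I/O, constant imputation and covariate subsets.

A :class:`Cohort` pairs a flat covariate table (53 columns: age, sex, 10
history binaries, 8 symptom binaries, 3 x 11 ECG lead columns) with outcome
labels (ACS indicator plus subtype STEMI / NSTEMI / UA / NONE).  Missing
covariate cells are represented as NaN until :func:`impute_constant` is
applied; CSV files encode missing cells as empty strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .schema import DEFAULT_SCHEMA, CovariateSchema

SUBTYPES = ("STEMI", "NSTEMI", "UA", "NONE")
NSTE_SUBTYPES = ("NSTEMI", "UA")
COHORT_TAGS = ("internal", "external", "synthetic")
LABEL_COLUMNS = ("acs", "subtype")
TROPONIN_COLUMN = "troponin_band"


@dataclass(frozen=True)
class OutcomeLabel:
    """Outcome for one patient: ACS indicator and subtype."""

    acs: int
    subtype: str

    def __post_init__(self) -> None:
        if self.acs not in (0, 1):
            raise ValidationError(f"acs must be 0/1, got {self.acs!r}")
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown subtype {self.subtype!r}")
        if (self.subtype == "NONE") != (self.acs == 0):
            raise ValidationError("subtype must be NONE iff acs == 0")

    @property
    def nste_acs(self) -> int:
        """1 iff the event is non-ST-elevation ACS (NSTEMI or UA)."""
        return int(self.subtype in NSTE_SUBTYPES)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, in schema terms (ECG as length-11 vectors)."""

    age: float
    gender_male: int
    history: dict[str, int]
    symptoms: dict[str, int]
    ecg_st_elevation: np.ndarray
    ecg_st_depression: np.ndarray
    ecg_t_wave_inversion: np.ndarray
    troponin_band: int | None = None
    missing: frozenset[str] = field(default_factory=frozenset)


@dataclass
class Cohort:
    """Covariates + labels for one cohort; NaN marks missing covariates."""

    covariates: pd.DataFrame
    labels: pd.DataFrame
    tag: str = "synthetic"
    troponin: pd.Series | None = None
    schema: CovariateSchema = field(default=DEFAULT_SCHEMA, repr=False)

    def __post_init__(self) -> None:
        if len(self.covariates) == 0:
            raise ValidationError("a cohort must contain at least one record")
        if len(self.covariates) != len(self.labels):
            raise ValidationError("covariates and labels differ in length")
        if self.tag not in COHORT_TAGS:
            raise ValidationError(f"unknown cohort tag {self.tag!r}")
        expected = self.schema.columns()
        if list(self.covariates.columns) != expected:
            raise SchemaError(
                "covariate columns do not match schema; first mismatch: "
                f"{_first_mismatch(list(self.covariates.columns), expected)}"
            )
        _validate_binary(self.covariates, self.schema)
        for acs, subtype in zip(self.labels["acs"], self.labels["subtype"]):
            OutcomeLabel(int(acs), str(subtype))  # raises on inconsistency

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.covariates.isna()

    @property
    def n_missing_cells(self) -> int:
        return int(self.missing_mask.to_numpy().sum())

    @property
    def acs(self) -> np.ndarray:
        return self.labels["acs"].to_numpy(dtype=int)

    @property
    def nste_acs(self) -> np.ndarray:
        return self.labels["subtype"].isin(NSTE_SUBTYPES).to_numpy(dtype=int)

    def task_labels(self, task: str) -> np.ndarray:
        """Binary outcome for a named task: ``acs`` or ``nste_acs``.

        The NSTE-ACS task counts NSTEMI and unstable angina as positive and
        everything else — including STEMI — as negative.
        """
        if task == "acs":
            return self.acs
        if task == "nste_acs":
            return self.nste_acs
        raise ValidationError(f"unknown task {task!r}; expected 'acs' or 'nste_acs'")

    def record(self, i: int) -> PatientRecord:
        row = self.covariates.iloc[i]
        ecg = {
            name: row[[f"{name}_L{j:02d}" for j in range(1, 12)]].to_numpy(dtype=float)
            for name in self.schema.names("ecg")
        }
        missing = frozenset(row.index[row.isna()])
        trop = None
        if self.troponin is not None:
            trop = int(self.troponin.iloc[i])
        return PatientRecord(
            age=float(row["age"]),
            gender_male=int(row["gender_male"]) if not np.isnan(row["gender_male"]) else 0,
            history={n: _as_bin(row[n]) for n in self.schema.names("history")},
            symptoms={n: _as_bin(row[n]) for n in self.schema.names("symptom")},
            ecg_st_elevation=ecg["ecg_st_elevation"],
            ecg_st_depression=ecg["ecg_st_depression"],
            ecg_t_wave_inversion=ecg["ecg_t_wave_inversion"],
            troponin_band=trop,
            missing=missing,
        )

    def label(self, i: int) -> OutcomeLabel:
        return OutcomeLabel(int(self.labels["acs"].iloc[i]), str(self.labels["subtype"].iloc[i]))


def _as_bin(v: float) -> int:
    return 0 if np.isnan(v) else int(v)


def _first_mismatch(got: list[str], expected: list[str]) -> str:
    for i, (g, e) in enumerate(zip(got, expected)):
        if g != e:
            return f"position {i}: {g!r} != {e!r}"
    return f"length {len(got)} != {len(expected)}"


def _validate_binary(df: pd.DataFrame, schema: CovariateSchema) -> None:
    for col in schema.binary_columns:
        vals = df[col]
        bad = ~(vals.isna() | vals.isin((0, 1)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-binary value {vals.iloc[row]!r} in column {col!r} at row {row}"
            )


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort_csv(
    path: str | Path, schema: CovariateSchema = DEFAULT_SCHEMA, tag: str = "synthetic"
) -> Cohort:
    """Read a cohort CSV (comma-separated, UTF-8, empty cell = missing).

    The file must carry one column per flat covariate (ECG vectors as 11
    columns suffixed ``_L01.._L11``), the label columns ``acs`` and
    ``subtype``, and optionally ``troponin_band``.
    """
    df = pd.read_csv(path, dtype={"subtype": str}, keep_default_na=True)
    expected = schema.columns() + list(LABEL_COLUMNS)
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: header lacks required columns {missing_cols}")
    cov = df[schema.columns()].astype(float)
    labels = pd.DataFrame(
        {"acs": df["acs"].astype(int), "subtype": df["subtype"].astype(str)}
    )
    trop = None
    if TROPONIN_COLUMN in df.columns:
        trop = df[TROPONIN_COLUMN].astype(int)
        trop.name = TROPONIN_COLUMN
    return Cohort(cov, labels, tag=tag, troponin=trop, schema=schema)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV; NaN covariates become empty cells."""
    parts = [cohort.covariates]
    if cohort.troponin is not None:
        parts.append(cohort.troponin.rename(TROPONIN_COLUMN))
    parts.append(cohort.labels)
    out = pd.concat(parts, axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation and covariate selection


def impute_constant(
    cohort: Cohort, numeric_fill: float = -1.0, binary_fill: int = 0
) -> Cohort:
    """Fill missing covariates with constants (idempotent).

    ``numeric_fill`` replaces missing numeric values (age); ``binary_fill``
    (0 or 1) replaces missing binaries.  Non-missing cells are untouched.
    """
    if binary_fill not in (0, 1):
        raise ValidationError(f"binary_fill must be 0 or 1, got {binary_fill!r}")
    cov = cohort.covariates.copy()
    num = cohort.schema.numeric_columns
    cov[num] = cov[num].fillna(float(numeric_fill))
    bins = cohort.schema.binary_columns
    cov[bins] = cov[bins].fillna(float(binary_fill))
    return replace(cohort, covariates=cov)


def select_covariates(cohort: Cohort, subset: str) -> pd.DataFrame:
    """Feature matrix (n x p) for a named covariate subset.

    Column order is deterministic: baseline (age, sex), ECG lead columns,
    then symptoms, then history, as the subsets nest.  ``hear_matched``
    collapses each ECG interpretation to an any-lead summary column.
    Requires an imputed cohort.
    """
    if cohort.missing_mask.to_numpy().any():
        raise ValidationError("cohort must be imputed before selecting covariates")
    cols = cohort.schema.subset_columns(subset)
    df = cohort.covariates
    if subset == "hear_matched":
        df = df.copy()
        for name in cohort.schema.names("ecg"):
            lead_cols = [f"{name}_L{j:02d}" for j in range(1, 12)]
            df[f"{name}_any"] = (df[lead_cols].sum(axis=1) > 0).astype(float)
    return df[cols].astype(float)
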