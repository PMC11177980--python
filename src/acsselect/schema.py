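"""Covariate schema for the prehospital chest-pain cohort.

The cohort carries 23 covariates: two baseline covariates (age in years and
male sex), ten medical-history binaries, eight presenting-symptom binaries,
and three ECG-interpretation vectors (ST elevation, ST depression, T-wave
inversion), each a per-lead {0,1} vector over 11 leads.  ECG vectors are
stored one column per lead, suffixed ``_L01`` .. ``_L11``, so the 23
covariates expand to 53 flat columns.

The canonical schema ships as a JSON asset (``data/covariate_schema.json``)
so external tooling can consume it without importing this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .exceptions import ConfigurationError, SchemaError

ECG_LEAD_COUNT = 11

#: covariate subsets used by the ablation study and the clinical-score
#: comparison; values are resolved lazily against the schema.
SUBSET_NAMES = (
    "baseline",
    "baseline_symptoms",
    "baseline_symptoms_history",
    "full",
    "hear_matched",
)


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    group: str  # baseline | history | symptom | ecg
    kind: str   # numeric | binary | binary_vector_11

    @property
    def columns(self) -> list[str]:
        """Flat column names this covariate occupies in a feature table."""
        if self.kind == "binary_vector_11":
            return [f"{self.name}_L{i:02d}" for i in range(1, ECG_LEAD_COUNT + 1)]
        return [self.name]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate schema; validates the 23-covariate contract."""

    entries: tuple[SchemaEntry, ...]

    def __post_init__(self) -> None:
        groups = {"baseline": 0, "history": 0, "symptom": 0, "ecg": 0}
        for e in self.entries:
            if e.group not in groups:
                raise SchemaError(f"unknown covariate group {e.group!r}")
            groups[e.group] += 1
        expected = {"baseline": 2, "history": 10, "symptom": 8, "ecg": 3}
        if groups != expected:
            raise SchemaError(f"covariate group counts {groups} != {expected}")
        if len(self.entries) != 23:
            raise SchemaError(f"expected 23 covariates, got {len(self.entries)}")

    # -- column bookkeeping -------------------------------------------------

    def names(self, group: str | None = None) -> list[str]:
        return [e.name for e in self.entries if group is None or e.group == group]

    def columns(self, group: str | None = None) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if group is None or e.group == group:
                out.extend(e.columns)
        return out

    @property
    def scalar_columns(self) -> list[str]:
        """The 20 non-vector columns (age plus 19 binaries)."""
        return [e.name for e in self.entries if e.kind != "binary_vector_11"]

    @property
    def binary_columns(self) -> list[str]:
        """Every column constrained to {0,1}: 19 scalar binaries + 33 lead columns."""
        return [c for e in self.entries if e.kind != "numeric" for c in e.columns]

    @property
    def numeric_columns(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "numeric"]

    def subset_columns(self, subset: str) -> list[str]:
        """Flat column list for a named covariate subset.

        Subsets are nested in the order baseline -> +symptoms -> +history so
        each adds columns to the previous.  ``full`` is an alias for
        ``baseline_symptoms_history``.  ``hear_matched`` is the reduced set
        the HEAR score consumes: age, sex, the symptoms feeding its history
        component, any-lead ECG summaries (see :func:`any_lead_columns`) and
        the nine risk-factor history binaries (angina is not a HEAR risk
        factor).
        """
        base = self.columns("baseline") + self.columns("ecg")
        if subset == "baseline":
            return base
        if subset == "baseline_symptoms":
            return base + self.columns("symptom")
        if subset in ("baseline_symptoms_history", "full"):
            return base + self.columns("symptom") + self.columns("history")
        if subset == "hear_matched":
            history = [n for n in self.names("history") if n != "angina"]
            return (
                ["age", "gender_male", "sym_chest_pain", "sym_diaphoresis",
                 "sym_nausea_vomiting"]
                + [f"{n}_any" for n in self.names("ecg")]
                + history
            )
        raise ConfigurationError(
            f"unknown covariate subset {subset!r}; expected one of {SUBSET_NAMES}"
        )


def load_schema() -> CovariateSchema:
    """Load the canonical schema from the packaged JSON asset."""
    text = resources.files("acsselect.data").joinpath("covariate_schema.json").read_text()
    raw = json.loads(text)
    return CovariateSchema(
        tuple(SchemaEntry(e["name"], e["group"], e["kind"]) for e in raw["entries"])
    )


#: module-level default schema; immutable, safe to share.
DEFAULT_SCHEMA = load_schema()
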