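"""Rule-based HEAR / HEART chest-pain score comparators.

HEART sums five 0-2-point components — History, ECG, Age, Risk factors,
Troponin — and HEAR drops the troponin component (the measurement is
generally unavailable before hospital arrival).  Bedside component
definitions involve clinical judgement the covariate schema cannot encode,
so each component is proxied from the available covariates by a documented,
editable mapping (``data/heart_components.json``):

* age: 0 / 1 / 2 points below 45 / 45-64 / at or over 65;
* risk factors: count of {hypercholesterolemia, hypertension, current
  smoker, diabetes, family history}; 0 -> 0 pts, 1-2 -> 1 pt, >=3 -> 2 pts;
  any atherosclerotic history (prior MI/PCI/CABG/CAD) forces 2;
* ECG: 2 points for any ST elevation or depression lead, 1 for T-wave
  inversion only, else 0;
* history: 2 points for chest pain with an autonomic symptom (diaphoresis
  or nausea/vomiting), 1 for chest pain alone, else 0;
* troponin (HEART only): the ordinal troponin band is the point value.

These scores are comparators for the uncertainty-guided exclusion
experiment, not a claim of clinical equivalence to bedside HEART scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .exceptions import ValidationError


def _load_mapping() -> dict:
    text = resources.files("acsselect.data").joinpath("heart_components.json").read_text()
    return json.loads(text)


DEFAULT_MAPPING = _load_mapping()


@dataclass(frozen=True)
class ScoreComponents:
    history_pts: int
    ecg_pts: int
    age_pts: int
    risk_pts: int
    troponin_pts: int | None = None

    def __post_init__(self) -> None:
        pts = [self.history_pts, self.ecg_pts, self.age_pts, self.risk_pts]
        if self.troponin_pts is not None:
            pts.append(self.troponin_pts)
        if any(p not in (0, 1, 2) for p in pts):
            raise ValidationError(f"score components must be 0/1/2, got {pts}")

    @property
    def hear(self) -> int:
        return self.history_pts + self.ecg_pts + self.age_pts + self.risk_pts

    @property
    def heart(self) -> int:
        if self.troponin_pts is None:
            raise ValidationError("HEART requires a troponin band")
        return self.hear + self.troponin_pts


def components(record: PatientRecord, mapping: dict = DEFAULT_MAPPING) -> ScoreComponents:
    """Score components for one patient record (must be imputed)."""
    if record.missing:
        raise ValidationError("record must be imputed before scoring")
    cuts = mapping["age_cutpoints"]
    age_pts = 0 if record.age < cuts["one_point_at"] else (
        1 if record.age < cuts["two_points_at"] else 2)
    n_risk = sum(record.history[f] for f in mapping["risk_factors"])
    rc = mapping["risk_counts"]
    risk_pts = 0 if n_risk < rc["one_point_at"] else (
        1 if n_risk < rc["two_points_at"] else 2)
    if any(record.history[f] for f in mapping["atherosclerotic_history"]):
        risk_pts = 2
    if record.ecg_st_elevation.any() or record.ecg_st_depression.any():
        ecg_pts = 2
    elif record.ecg_t_wave_inversion.any():
        ecg_pts = 1
    else:
        ecg_pts = 0
    chest = record.symptoms[mapping["history_primary_symptom"]]
    autonomic = any(record.symptoms[s] for s in mapping["history_supporting_symptoms"])
    history_pts = 2 if (chest and autonomic) else (1 if chest else 0)
    return ScoreComponents(history_pts, ecg_pts, age_pts, risk_pts,
                           troponin_pts=record.troponin_band)


def hear_score(record: PatientRecord, mapping: dict = DEFAULT_MAPPING) -> int:
    """HEAR score in [0, 8]."""
    return components(record, mapping).hear


def heart_score(record: PatientRecord, mapping: dict = DEFAULT_MAPPING) -> int:
    """HEART score in [0, 10]; requires a troponin band on the record."""
    c = components(record, mapping)
    if c.troponin_pts is None:
        raise ValidationError("HEART requires a troponin band on the record")
    return c.heart


def _cohort_components(cohort: Cohort, mapping: dict) -> pd.DataFrame:
    """Vectorised component table for a whole cohort."""
    df = cohort.covariates
    if df.isna().to_numpy().any():
        raise ValidationError("cohort must be imputed before scoring")
    cuts = mapping["age_cutpoints"]
    age_pts = np.select(
        [df["age"] < cuts["one_point_at"], df["age"] < cuts["two_points_at"]],
        [0, 1], default=2,
    )
    n_risk = df[mapping["risk_factors"]].sum(axis=1)
    rc = mapping["risk_counts"]
    risk_pts = np.select(
        [n_risk < rc["one_point_at"], n_risk < rc["two_points_at"]], [0, 1], default=2
    )
    athero = df[mapping["atherosclerotic_history"]].sum(axis=1) > 0
    risk_pts = np.where(athero, 2, risk_pts)
    lead = lambda name: df[[f"{name}_L{j:02d}" for j in range(1, 12)]].sum(axis=1) > 0
    st = lead("ecg_st_elevation") | lead("ecg_st_depression")
    twi = lead("ecg_t_wave_inversion")
    ecg_pts = np.select([st, twi], [2, 1], default=0)
    chest = df[mapping["history_primary_symptom"]] == 1
    autonomic = df[mapping["history_supporting_symptoms"]].sum(axis=1) > 0
    history_pts = np.select([chest & autonomic, chest], [2, 1], default=0)
    return pd.DataFrame(
        {"history_pts": history_pts, "ecg_pts": ecg_pts,
         "age_pts": age_pts, "risk_pts": risk_pts}
    )


def hear_scores(cohort: Cohort, mapping: dict = DEFAULT_MAPPING) -> np.ndarray:
    """HEAR score per patient, vectorised."""
    return _cohort_components(cohort, mapping).sum(axis=1).to_numpy()


def heart_scores(cohort: Cohort, mapping: dict = DEFAULT_MAPPING) -> np.ndarray:
    """HEART score per patient; requires cohort troponin bands."""
    if cohort.troponin is None:
        raise ValidationError("HEART requires troponin bands on the cohort")
    return hear_scores(cohort, mapping) + cohort.troponin.to_numpy()


def score_as_classifier(scores) -> np.ndarray:
    """Use raw integer scores as an AUROC ranking statistic (ties 1/2)."""
    return np.asarray(scores, dtype=float)
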