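"""NCEP ATP III metabolic syndrome classification.

A subject is positive when at least ``required_count`` (default 3) of
five criteria are met: abdominal obesity (sex-specific waist cut,
strict >), elevated triglycerides (≥150 mg/dl), low HDL (sex-specific,
<40/<50 mg/dl), elevated blood pressure (≥130/85 mmHg or treated), and
elevated fasting glucose (≥100 mg/dl by default; the original 110 cut
is available through :class:`MetsCriteria`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import pandas as pd

from .cohort import Cohort, SubjectRecord
from .errors import MissingDataError

__all__ = ["MetsCriteria", "MetsResult", "classify_mets", "classify_table"]


@dataclass(frozen=True)
class MetsCriteria:
    """Thresholds of the five ATP III criteria; all overridable."""

    wc_cut_male: float = 102.0
    wc_cut_female: float = 88.0
    tg_cut: float = 150.0
    hdl_cut_male: float = 40.0
    hdl_cut_female: float = 50.0
    sbp_cut: float = 130.0
    dbp_cut: float = 85.0
    glucose_cut: float = 100.0
    required_count: int = 3

    def __post_init__(self):
        for f in dc_fields(self):
            if f.name != "required_count" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not 1 <= self.required_count <= 5:
            raise ValueError("required_count must be in 1..5")


@dataclass(frozen=True)
class MetsResult:
    """Per-criterion flags; ``positive`` iff met_count ≥ required_count."""

    abdominal: bool
    triglyceride: bool
    hdl: bool
    blood_pressure: bool
    glucose: bool
    met_count: int
    positive: bool

    @property
    def flags(self) -> tuple:
        return (self.abdominal, self.triglyceride, self.hdl,
                self.blood_pressure, self.glucose)


def classify_mets(record: SubjectRecord,
                  criteria: MetsCriteria = MetsCriteria()) -> MetsResult:
    """Classify one subject; raises MissingDataError listing every absent
    required field (sex, wc, tg, hdl, sbp, dbp, glucose)."""
    record.require("sex", "wc", "tg", "hdl", "sbp", "dbp", "glucose")
    male = record.sex == "male"
    abdominal = record.wc > (criteria.wc_cut_male if male else criteria.wc_cut_female)
    triglyceride = record.tg >= criteria.tg_cut
    hdl = record.hdl < (criteria.hdl_cut_male if male else criteria.hdl_cut_female)
    blood_pressure = (record.sbp >= criteria.sbp_cut or record.dbp >= criteria.dbp_cut
                      or bool(record.bp_treated))
    glucose = record.glucose >= criteria.glucose_cut
    flags = (abdominal, triglyceride, hdl, blood_pressure, glucose)
    met_count = sum(flags)
    return MetsResult(*flags, met_count=met_count,
                      positive=met_count >= criteria.required_count)


def classify_table(cohort: Cohort,
                   criteria: MetsCriteria = MetsCriteria()) -> pd.DataFrame:
    """Cohort-level classification table, row order preserved."""
    rows = []
    for rec in cohort:
        res = classify_mets(rec, criteria)
        rows.append({
            "subject_id": rec.subject_id,
            "abdominal": res.abdominal, "triglyceride": res.triglyceride,
            "hdl": res.hdl, "blood_pressure": res.blood_pressure,
            "glucose": res.glucose, "met_count": res.met_count,
            "positive": res.positive,
        })
    return pd.DataFrame(rows)
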