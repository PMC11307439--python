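"""Comparator adiposity indices with explicit unit contracts.

Storage units are cm / kg / mg/dl throughout the package; the formulas
below convert internally where an index is defined on mmol/l (VAI, LAP)
or metres (ABSI, BRI).  Sex-specific branches follow the original index
definitions: VAI and LAP have separate male/female constants, METS-VF
carries a male offset (+0.319).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectRecord, bmi as _bmi, mgdl_to_mmoll
from .errors import DomainError, MissingDataError

__all__ = [
    "IndexValue",
    "vai", "lap", "absi", "bri", "mets_ir", "mets_vf", "whr", "whtr",
    "bmi_index", "compute_all", "compute_table", "INDEX_NAMES",
]

INDEX_NAMES = ("VAI", "LAP", "ABSI", "BRI", "METS_IR", "METS_VF", "WHR", "WHtR", "BMI")


@dataclass(frozen=True)
class IndexValue:
    """One computed index: name, value and the inputs it consumed."""

    name: str
    value: float
    inputs_used: tuple = ()
    note: str = ""


def vai(record: SubjectRecord) -> IndexValue:
    """Visceral adiposity index (sex-specific; TG and HDL in mmol/l).

    male:   WC/(39.68 + 1.88·BMI) · (TG/1.03) · (1.31/HDL)
    female: WC/(36.58 + 1.89·BMI) · (TG/0.81) · (1.52/HDL)
    """
    record.require("sex", "wc", "tg", "hdl")
    if record.tg <= 0 or record.hdl <= 0:
        raise DomainError("VAI needs strictly positive TG and HDL")
    b = record.bmi
    tg = mgdl_to_mmoll(record.tg, "triglyceride")
    hdl = mgdl_to_mmoll(record.hdl, "cholesterol")
    if record.sex == "male":
        value = record.wc / (39.68 + 1.88 * b) * (tg / 1.03) * (1.31 / hdl)
    else:
        value = record.wc / (36.58 + 1.89 * b) * (tg / 0.81) * (1.52 / hdl)
    return IndexValue("VAI", value, ("sex", "wc", "height", "weight", "tg", "hdl"))


def lap(record: SubjectRecord) -> IndexValue:
    """Lipid accumulation product: (WC − 65)·TG for men, (WC − 58)·TG for
    women, TG in mmol/l.  Negative when WC is below the sex constant;
    flagged in ``note`` rather than truncated."""
    record.require("sex", "wc", "tg")
    tg = mgdl_to_mmoll(record.tg, "triglyceride")
    anchor = 65.0 if record.sex == "male" else 58.0
    value = (record.wc - anchor) * tg
    note = "negative: WC below sex anchor" if value < 0 else ""
    return IndexValue("LAP", value, ("sex", "wc", "tg"), note)


def absi(record: SubjectRecord) -> IndexValue:
    """A body shape index: WC(m) / (BMI^(2/3) · height(m)^(1/2))."""
    record.require("wc", "height", "weight")
    b = record.bmi
    value = (record.wc / 100.0) / (b ** (2.0 / 3.0) * (record.height / 100.0) ** 0.5)
    return IndexValue("ABSI", value, ("wc", "height", "weight"))


def bri(record: SubjectRecord) -> IndexValue:
    """Body roundness index:
    364.2 − 365.5·sqrt(1 − (WC/2π)² / (0.5·height)²), WC and height in
    the same length unit (scale-invariant)."""
    record.require("wc", "height")
    ecc = 1.0 - (record.wc / (2.0 * math.pi)) ** 2 / (0.5 * record.height) ** 2
    if ecc < 0:
        raise DomainError("BRI undefined: waist circumference / pi exceeds height")
    value = 364.2 - 365.5 * math.sqrt(ecc)
    return IndexValue("BRI", value, ("wc", "height"))


def mets_ir(record: SubjectRecord) -> IndexValue:
    """Metabolic score for insulin resistance:
    ln(2·glucose + TG) · BMI / ln(HDL), everything in mg/dl."""
    record.require("glucose", "tg", "hdl", "height", "weight")
    if 2.0 * record.glucose + record.tg <= 0:
        raise DomainError("METS-IR needs 2·glucose + TG > 0")
    if record.hdl <= 1.0:
        raise DomainError("METS-IR needs HDL > 1 mg/dl")
    value = math.log(2.0 * record.glucose + record.tg) * record.bmi / math.log(record.hdl)
    return IndexValue("METS_IR", value, ("glucose", "tg", "hdl", "height", "weight"))


def mets_vf(record: SubjectRecord) -> IndexValue:
    """Metabolic score for visceral fat:
    4.466 + 0.011·(ln METS-IR)³ + 3.239·(ln WHtR)³ + 0.319·[male] + 0.594·ln(age)."""
    record.require("age", "wc", "height")
    mir = mets_ir(record).value
    if mir <= 0:
        raise DomainError("METS-VF needs METS-IR > 0")
    ratio = record.wc / record.height
    sex_term = 1.0 if record.sex == "male" else 0.0
    value = (4.466 + 0.011 * math.log(mir) ** 3 + 3.239 * math.log(ratio) ** 3
             + 0.319 * sex_term + 0.594 * math.log(record.age))
    return IndexValue("METS_VF", value,
                      ("sex", "age", "wc", "height", "weight", "glucose", "tg", "hdl"))


def whr(record: SubjectRecord) -> IndexValue:
    """Waist-to-hip ratio."""
    record.require("wc", "hc")
    return IndexValue("WHR", record.wc / record.hc, ("wc", "hc"))


def whtr(record: SubjectRecord) -> IndexValue:
    """Waist-to-height ratio (also the WHtR input of METS-VF)."""
    record.require("wc", "height")
    return IndexValue("WHtR", record.wc / record.height, ("wc", "height"))


def bmi_index(record: SubjectRecord) -> IndexValue:
    """BMI packaged as an index value (kg/m²)."""
    return IndexValue("BMI", _bmi(record), ("height", "weight"))


_INDEX_FUNCS: Dict[str, Callable[[SubjectRecord], IndexValue]] = {
    "VAI": vai, "LAP": lap, "ABSI": absi, "BRI": bri,
    "METS_IR": mets_ir, "METS_VF": mets_vf, "WHR": whr, "WHtR": whtr,
    "BMI": bmi_index,
}


def compute_all(record: SubjectRecord):
    """Every computable index for one subject.

    Returns ``(values, absent)``: a dict name → IndexValue and a dict
    name → reason for indices whose inputs are missing or out of domain.
    """
    values, absent = {}, {}
    for name, fn in _INDEX_FUNCS.items():
        try:
            values[name] = fn(record)
        except (MissingDataError, DomainError) as exc:
            absent[name] = str(exc)
    return values, absent


def compute_table(cohort: Cohort) -> pd.DataFrame:
    """Row-order-preserving index table for a cohort; one column per
    index plus ``<index>_absent_reason`` columns for unavailable values."""
    rows = []
    for rec in cohort:
        values, absent = compute_all(rec)
        row = {"subject_id": rec.subject_id}
        for name in INDEX_NAMES:
            row[name] = values[name].value if name in values else np.nan
            row[f"{name}_absent_reason"] = absent.get(name, "")
        rows.append(row)
    return pd.DataFrame(rows)
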