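"""Subject data model, unit conversions, validation and CSV round-tripping.

All quantities are stored in one canonical unit system: lengths in cm,
weight in kg, blood pressure in mmHg, lipids and glucose in mg/dl.
Index formulas that need SI units (mmol/l, metres) convert internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

from .errors import CohortValidationError, MissingDataError, SchemaError, VatPredictError

__all__ = [
    "SubjectRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "bmi",
    "mgdl_to_mmoll",
    "mmoll_to_mgdl",
    "TG_MGDL_PER_MMOLL",
    "CHOL_MGDL_PER_MMOLL",
]

#: mg/dl per mmol/l; molecular-weight based, overridable via function argument.
TG_MGDL_PER_MMOLL = 88.57
CHOL_MGDL_PER_MMOLL = 38.67

REQUIRED_FIELDS = ("sex", "age", "height", "weight", "wc", "hc")
OPTIONAL_NUMERIC_FIELDS = (
    "sbp", "dbp", "glucose", "tg", "hdl", "ldl", "c_peptide", "ct_vat", "ct_sat",
)
# (lo, hi) hard plausibility bounds enforced at validation; open on None.
_BOUNDS = {
    "age": (18.0, 120.0),
    "height": (0.0, None),
    "weight": (0.0, None),
    "wc": (0.0, None),
    "hc": (0.0, None),
    "sbp": (0.0, None),
    "dbp": (0.0, None),
    "glucose": (0.0, None),
    "tg": (0.0, None),
    "hdl": (0.0, None),
    "ldl": (0.0, None),
    "c_peptide": (0.0, None),
    "ct_vat": (0.0, None),
    "ct_sat": (0.0, None),
}


@dataclass(frozen=True)
class SubjectRecord:
    """One person's anthropometric and laboratory measurements.

    Required: ``sex`` ("male"/"female"), ``age`` (years), ``height`` (cm),
    ``weight`` (kg), ``wc`` and ``hc`` (waist/hip circumference, cm).
    Laboratory values (``glucose``, ``tg``, ``hdl`` in mg/dl), blood
    pressures (mmHg) and CT adipose areas (cm²) are optional and stay
    ``None`` when unmeasured; operations that need them raise
    :class:`~vatpredict.errors.MissingDataError`.
    """

    subject_id: str
    sex: str
    age: float
    height: float
    weight: float
    wc: float
    hc: float
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    glucose: Optional[float] = None
    tg: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    c_peptide: Optional[float] = None
    bp_treated: bool = False
    ct_vat: Optional[float] = None
    ct_sat: Optional[float] = None

    @property
    def bmi(self) -> float:
        return bmi(self)

    def require(self, *names: str) -> None:
        """Raise MissingDataError listing every absent field among *names*."""
        missing = [n for n in names if getattr(self, n, None) is None]
        if missing:
            raise MissingDataError(missing, context=f"subject {self.subject_id}")

    def replace(self, **kwargs) -> "SubjectRecord":
        return replace(self, **kwargs)


def _validate_record_dict(row: Mapping, idx) -> list:
    """Return (row, field, message) diagnostics for one raw row."""
    diags = []
    sex = row.get("sex")
    if sex not in ("male", "female"):
        diags.append((idx, "sex", f"expected 'male' or 'female', got {sex!r}"))
    for name in REQUIRED_FIELDS[1:] + OPTIONAL_NUMERIC_FIELDS:
        val = row.get(name)
        if val is None:
            if name in REQUIRED_FIELDS:
                diags.append((idx, name, "required value absent"))
            continue
        if not math.isfinite(val):
            diags.append((idx, name, "non-finite value"))
            continue
        lo, hi = _BOUNDS[name]
        if name == "age":
            if not (lo <= val <= hi):
                diags.append((idx, name, f"value {val} outside [{lo}, {hi}]"))
        elif val <= lo or (hi is not None and val > hi):
            diags.append((idx, name, f"value {val} outside ({lo}, {hi or 'inf'}]"))
    return diags


@dataclass
class Cohort:
    """An ordered collection of validated :class:`SubjectRecord` objects."""

    records: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(
                [("-", "subject_id", f"duplicate id {d!r}") for d in dupes]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; absent optional values become NaN, bmi is derived."""
        cols = [f.name for f in dc_fields(SubjectRecord)]
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        df = pd.DataFrame(data, columns=cols)
        df["bmi"] = [r.bmi for r in self.records]
        return df


_FIELD_PARSERS = {"subject_id": str, "sex": str, "bp_treated": None}


def _parse_cell(name: str, raw):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str) and raw.strip() == "":
        return None
    if name in ("subject_id", "sex"):
        return str(raw).strip()
    if name == "bp_treated":
        s = str(raw).strip().lower()
        if s in ("1", "true", "yes", "y"):
            return True
        if s in ("0", "false", "no", "n", ""):
            return False
        raise ValueError(f"unparseable flag {raw!r}")
    return float(raw)


def read_cohort(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    label: str = "",
    on_invalid: str = "raise",
) -> Cohort:
    """Read a cohort CSV into validated records.

    Parameters
    ----------
    path : file path of a comma-separated, UTF-8, headered table.
    column_map : optional mapping {canonical field: source column name}.
    on_invalid : "raise" (default) aborts with all diagnostics; "drop"
        silently rejects offending rows (diagnostics attached to the
        returned cohort as ``.dropped``).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {src: canon for canon, src in column_map.items()}
    df = df.rename(columns=rename)
    missing_cols = [c for c in REQUIRED_FIELDS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    known = {f.name for f in dc_fields(SubjectRecord)}
    records, diagnostics, dropped = [], [], []
    for idx, raw in enumerate(df.to_dict(orient="records")):
        row, row_diags = {}, []
        for name in known:
            if name not in raw:
                continue
            try:
                row[name] = _parse_cell(name, raw[name])
            except ValueError:
                row_diags.append((idx, name, f"non-numeric value {raw[name]!r}"))
        if "subject_id" not in row or row.get("subject_id") is None:
            row["subject_id"] = str(idx)
        row_diags.extend(_validate_record_dict(row, idx))
        if row_diags:
            diagnostics.extend(row_diags)
            dropped.append(idx)
            continue
        defaults = {"bp_treated": False}
        records.append(SubjectRecord(**{**defaults, **{k: v for k, v in row.items() if v is not None or k not in defaults}}))
    if diagnostics and on_invalid == "raise":
        raise CohortValidationError(diagnostics)
    cohort = Cohort(records=records, label=label or str(path))
    cohort.dropped = diagnostics  # type: ignore[attr-defined]
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; read_cohort(write_cohort(c)) is the identity
    on all present fields (absent optionals round-trip as empty cells)."""
    cols = [f.name for f in dc_fields(SubjectRecord)]
    rows = []
    for r in cohort.records:
        row = {}
        for c in cols:
            v = getattr(r, c)
            if c == "bp_treated":
                v = "true" if v else "false"
            row[c] = "" if v is None else v
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise VatPredictError(f"cannot write cohort to {path}: {exc}") from exc


def cohort_from_frame(df: pd.DataFrame, label: str = "") -> Cohort:
    """Build a cohort from an in-memory table with canonical column names."""
    records = []
    for idx, raw in df.iterrows():
        row = {}
        for f in dc_fields(SubjectRecord):
            if f.name in df.columns:
                val = raw[f.name]
                if isinstance(val, float) and math.isnan(val):
                    val = None
                row[f.name] = val
        row.setdefault("subject_id", str(idx))
        if row.get("bp_treated") is None:
            row["bp_treated"] = False
        diags = _validate_record_dict(row, idx)
        if diags:
            raise CohortValidationError(diags)
        records.append(SubjectRecord(**row))
    return Cohort(records=records, label=label)


def bmi(record) -> float:
    """Body mass index, weight(kg) / height(m)², from a record or row-like."""
    h = getattr(record, "height", None)
    w = getattr(record, "weight", None)
    if h is None or w is None:
        raise MissingDataError([n for n, v in (("height", h), ("weight", w)) if v is None])
    return w / (h / 100.0) ** 2


def mgdl_to_mmoll(value: float, analyte: str,
                  tg_factor: float = TG_MGDL_PER_MMOLL,
                  chol_factor: float = CHOL_MGDL_PER_MMOLL) -> float:
    """Convert a lipid concentration from mg/dl to mmol/l."""
    if value < 0:
        raise VatPredictError(f"negative concentration {value}")
    if analyte == "triglyceride":
        return value / tg_factor
    if analyte == "cholesterol":
        return value / chol_factor
    raise ValueError(f"unknown analyte {analyte!r}; use 'triglyceride' or 'cholesterol'")


def mmoll_to_mgdl(value: float, analyte: str,
                  tg_factor: float = TG_MGDL_PER_MMOLL,
                  chol_factor: float = CHOL_MGDL_PER_MMOLL) -> float:
    """Inverse of :func:`mgdl_to_mmoll` (exact to floating-point round-off)."""
    if analyte == "triglyceride":
        return value * tg_factor
    if analyte == "cholesterol":
        return value * chol_factor
    raise ValueError(f"unknown analyte {analyte!r}")
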