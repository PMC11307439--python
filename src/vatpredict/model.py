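"""MARS model representation and evaluation for VAT prediction.

A model is a constant (cm²) plus coefficient-weighted basis functions,
each a product of at most two factors: a hinge ``max(0, ±(x − knot))``
on a continuous predictor or an indicator on a categorical one.  The
published anthropometric VAT predictor (waist circumference, hip
circumference, BMI, sex) ships as a packaged JSON fixture and is
returned by :func:`published_vat_model`.

Evaluation accepts either a :class:`~vatpredict.cohort.SubjectRecord`
(BMI derived from height and weight) or a plain mapping / DataFrame row
with canonical predictor names.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectRecord
from .errors import MissingDataError, VatPredictError

__all__ = [
    "HingeFactor",
    "IndicatorFactor",
    "BasisFunction",
    "MarsModel",
    "published_vat_model",
    "evaluate_basis",
    "predict_vat",
    "predict_vat_batch",
    "PlausibilityWarning",
]

#: Predictions outside this range (cm²) trigger a plausibility warning;
#: physiological limits for an L3-slice VAT area.
VAT_PLAUSIBLE_RANGE = (0.0, 700.0)


class PlausibilityWarning(UserWarning):
    """Prediction outside the physiologically plausible VAT range."""


@dataclass(frozen=True)
class HingeFactor:
    """``max(0, knot − x)`` (direction "below") or ``max(0, x − knot)``."""

    variable: str
    knot: float
    direction: str  # "below" | "above"

    def __post_init__(self):
        if self.direction not in ("below", "above"):
            raise ValueError(f"direction must be below/above, got {self.direction!r}")
        if not math.isfinite(self.knot):
            raise ValueError("knot must be finite")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.direction == "below":
            return np.maximum(0.0, self.knot - x)
        return np.maximum(0.0, x - self.knot)

    def to_dict(self):
        return {"kind": "hinge", "variable": self.variable,
                "knot": self.knot, "direction": self.direction}


@dataclass(frozen=True)
class IndicatorFactor:
    """1 when the categorical variable equals ``level``, else 0."""

    variable: str
    level: str

    def __call__(self, x):
        return (np.asarray(x) == self.level).astype(float)

    def to_dict(self):
        return {"kind": "indicator", "variable": self.variable, "level": self.level}


Factor = Union[HingeFactor, IndicatorFactor]


@dataclass(frozen=True)
class BasisFunction:
    """Coefficient times a product of 1–2 factors on distinct variables."""

    coefficient: float
    factors: tuple

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        if not 1 <= len(self.factors) <= 2:
            raise ValueError("basis function degree must be 1 or 2")
        vars_ = [f.variable for f in self.factors]
        if len(set(vars_)) != len(vars_):
            raise ValueError("a variable may appear in only one factor of a term")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> tuple:
        return tuple(f.variable for f in self.factors)

    def to_dict(self):
        return {"coefficient": self.coefficient,
                "factors": [f.to_dict() for f in self.factors]}


@dataclass(frozen=True)
class MarsModel:
    """Constant plus ordered basis functions; piecewise-linear, continuous."""

    constant: float
    basis_functions: tuple
    response_name: str = "ct_vat"

    def __post_init__(self):
        object.__setattr__(self, "basis_functions", tuple(self.basis_functions))

    @property
    def variables(self) -> tuple:
        seen = []
        for bf in self.basis_functions:
            for v in bf.variables:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    @property
    def max_degree(self) -> int:
        return max((bf.degree for bf in self.basis_functions), default=0)

    # -- serialization -------------------------------------------------
    def to_dict(self):
        return {"response_name": self.response_name, "constant": self.constant,
                "basis_functions": [bf.to_dict() for bf in self.basis_functions]}

    def to_json(self, path=None, **kwargs) -> str:
        doc = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MarsModel":
        bfs = []
        for raw in doc["basis_functions"]:
            factors = []
            for f in raw["factors"]:
                if f["kind"] == "hinge":
                    factors.append(HingeFactor(f["variable"], float(f["knot"]), f["direction"]))
                elif f["kind"] == "indicator":
                    factors.append(IndicatorFactor(f["variable"], f["level"]))
                else:
                    raise VatPredictError(f"unknown factor kind {f['kind']!r}")
            bfs.append(BasisFunction(float(raw["coefficient"]), tuple(factors)))
        return cls(constant=float(doc["constant"]), basis_functions=tuple(bfs),
                   response_name=doc.get("response_name", "ct_vat"))

    @classmethod
    def from_json(cls, path) -> "MarsModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    # -- evaluation ----------------------------------------------------
    def design_matrix(self, table: pd.DataFrame) -> np.ndarray:
        """n × (1 + n_terms) basis expansion (intercept first)."""
        cols = [np.ones(len(table))]
        for bf in self.basis_functions:
            col = np.ones(len(table))
            for f in bf.factors:
                col = col * f(table[f.variable].to_numpy())
            cols.append(col)
        return np.column_stack(cols)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise MissingDataError(missing)
        B = self.design_matrix(table)
        coefs = np.concatenate([[self.constant],
                                [bf.coefficient for bf in self.basis_functions]])
        return B @ coefs


def _record_env(record) -> dict:
    """Flatten a record/mapping into {predictor: value}, deriving bmi."""
    if isinstance(record, SubjectRecord):
        env = {"subject_id": record.subject_id, "sex": record.sex, "age": record.age,
               "height": record.height, "weight": record.weight,
               "wc": record.wc, "hc": record.hc, "sbp": record.sbp,
               "dbp": record.dbp, "glucose": record.glucose, "tg": record.tg,
               "hdl": record.hdl, "c_peptide": record.c_peptide,
               "ct_vat": record.ct_vat}
        env["bmi"] = record.bmi
        return env
    env = dict(record)
    h, w = env.get("height"), env.get("weight")
    if h is not None and w is not None and not (pd.isna(h) or pd.isna(w)):
        computed = w / (h / 100.0) ** 2
        supplied = env.get("bmi")
        if supplied is not None and not pd.isna(supplied) and abs(supplied - computed) > 0.1:
            warnings.warn(
                f"supplied bmi {supplied:.2f} disagrees with computed {computed:.2f}; "
                "using the computed value", UserWarning)
        env["bmi"] = computed
    return env


def published_vat_model() -> MarsModel:
    """The published final VAT model (constant 249 cm² plus 7 basis functions
    over sex, waist circumference, hip circumference and BMI)."""
    ref = resources.files("vatpredict").joinpath("data/published_vat_model.json")
    with ref.open(encoding="utf-8") as fh:
        return MarsModel.from_dict(json.load(fh))


def evaluate_basis(bf: BasisFunction, record) -> float:
    """Contribution (cm²) of one basis function for one subject."""
    env = _record_env(record)
    value = bf.coefficient
    for f in bf.factors:
        x = env.get(f.variable)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise MissingDataError(f.variable)
        value *= float(f(x))
    return value


def predict_vat(model: MarsModel, record, warn_implausible: bool = True) -> float:
    """Predicted VAT area (cm²) for one subject; continuous and piecewise
    linear in every continuous predictor."""
    env = _record_env(record)
    missing = [v for v in model.variables
               if env.get(v) is None or (isinstance(env.get(v), float) and math.isnan(env[v]))]
    if missing:
        raise MissingDataError(missing)
    total = model.constant
    for bf in model.basis_functions:
        value = bf.coefficient
        for f in bf.factors:
            value *= float(f(env[f.variable]))
        total += value
    if warn_implausible and not VAT_PLAUSIBLE_RANGE[0] <= total <= VAT_PLAUSIBLE_RANGE[1]:
        warnings.warn(f"predicted VAT {total:.1f} cm² outside plausible range "
                      f"{VAT_PLAUSIBLE_RANGE}", PlausibilityWarning)
    return total


def predict_vat_batch(model: MarsModel, cohort: Cohort, skip_invalid: bool = False):
    """Order-preserving predictions for a cohort.

    Returns ``(predictions, report)`` where ``predictions`` is a pandas
    Series indexed by subject_id (skipped subjects absent) and ``report``
    lists ``(subject_id, reason)`` for rows that could not be scored.
    """
    preds, index, report = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlausibilityWarning)
        for rec in cohort:
            try:
                preds.append(predict_vat(model, rec))
                index.append(rec.subject_id)
            except MissingDataError as exc:
                if not skip_invalid:
                    raise
                report.append((rec.subject_id, f"{', '.join(exc.fields)} absent"))
    if len(cohort) and not preds and skip_invalid:
        raise VatPredictError("no row in the cohort could be scored")
    return pd.Series(preds, index=index, name="predicted_vat", dtype=float), report
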