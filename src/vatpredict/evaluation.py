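"""ROC analysis with DeLong variance, cutoff selection, goodness-of-fit
and calibration metrics.

The AUC is the Mann–Whitney placement estimator (ties count 1/2); its
standard error and the paired-AUC test follow DeLong, DeLong & Clarke-
Pearson (1988): per-observation placement components give the variance
of one AUC (S10/m + S01/n) and the covariance of two correlated AUCs
estimated on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .errors import DegenerateInputError, DomainError, VatPredictError

__all__ = [
    "RocResult", "DelongComparison", "GofReport", "CalibrationReport",
    "IncreasedVatRule", "roc", "delong_paired_test", "operating_point",
    "select_cutoff", "compare_indices", "gof", "calibration",
]


@dataclass(frozen=True)
class IncreasedVatRule:
    """Dichotomizes measured VAT; default literature cutoff 130 cm²."""

    threshold: float = 130.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def __call__(self, ct_vat):
        return np.asarray(ct_vat, dtype=float) > self.threshold


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    case_placements: np.ndarray
    control_placements: np.ndarray
    n_cases: int
    n_controls: int
    curve: np.ndarray  # (k, 2) of (1-specificity, sensitivity)

    @property
    def var(self) -> float:
        return self.se ** 2


@dataclass(frozen=True)
class DelongComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p: float


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        labels = labels.astype(int)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise DegenerateInputError("both outcome classes must be represented")
    return labels.astype(int)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement components V10 (cases) and V01 (controls)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    mid = stats.rankdata(combined, method="average")
    r_cases = stats.rankdata(cases, method="average")
    r_controls = stats.rankdata(controls, method="average")
    # placement of case i among controls: (midrank within pool − rank within own class)/n
    v10 = (mid[:m] - r_cases) / n
    v01 = 1.0 - (mid[m:] - r_controls) / m
    return v10, v01, cases, controls


def roc(scores, labels) -> RocResult:
    """AUC with DeLong standard error and the empirical ROC step curve."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    labels = _check_labels(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    v10, v01, cases, controls = _placements(scores, labels)
    m, n = cases.size, controls.size
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))

    # step curve over descending unique thresholds
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    curve = np.column_stack([np.r_[0.0, fps / n], np.r_[0.0, tps / m]])
    return RocResult(auc=auc, se=se, case_placements=v10, control_placements=v01,
                     n_cases=m, n_controls=n, curve=curve)


def delong_paired_test(scores_a, scores_b, labels) -> DelongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    z = (AUC_a − AUC_b) / sqrt(var_a + var_b − 2 cov); two-sided normal p.
    Identical scores give z = 0, p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("scores_a and scores_b must have equal length")
    labels = _check_labels(labels)
    ra = roc(scores_a, labels)
    rb = roc(scores_b, labels)
    m, n = ra.n_cases, ra.n_controls
    if m > 1:
        cov10 = np.cov(ra.case_placements, rb.case_placements, ddof=1)[0, 1]
    else:
        cov10 = 0.0
    if n > 1:
        cov01 = np.cov(ra.control_placements, rb.control_placements, ddof=1)[0, 1]
    else:
        cov01 = 0.0
    cov = cov10 / m + cov01 / n
    var_diff = ra.var + rb.var - 2.0 * cov
    delta = ra.auc - rb.auc
    if var_diff <= 0 or np.isclose(var_diff, 0.0, atol=1e-15):
        if np.isclose(delta, 0.0, atol=1e-12):
            z, p = 0.0, 1.0
        else:
            raise DomainError("zero variance of the AUC difference with unequal AUCs")
    else:
        z = float(delta / np.sqrt(var_diff))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongComparison(auc_a=ra.auc, auc_b=rb.auc, var_a=ra.var, var_b=rb.var,
                            covariance=cov, z=z, p=min(p, 1.0))


def operating_point(scores, labels, cutoff: float):
    """(sensitivity, specificity) calling positive when score ≥ cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    calls = scores >= cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def select_cutoff(scores, labels):
    """Cutoff maximizing Youden's J over observed score values.

    Ties are broken by minimal |sensitivity − specificity|, then by the
    smaller cutoff.  Returns ``(cutoff, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    best = None
    for c in np.unique(scores):
        sens, spec = operating_point(scores, labels, c)
        j = sens + spec - 1.0
        key = (-j, abs(sens - spec), c)
        if best is None or key < best[0]:
            best = (key, c, sens, spec)
    return best[1], best[2], best[3]


def compare_indices(cohort: Cohort, rule: IncreasedVatRule,
                    markers: Mapping[str, Sequence[float]], reference: str,
                    stratify_by_sex: bool = True) -> pd.DataFrame:
    """AUC ± SE per marker and DeLong p versus the reference marker.

    The outcome is measured VAT above ``rule.threshold``.  Strata with a
    single outcome class are skipped with a warning row.  Marker score
    vectors must align with cohort row order.
    """
    if reference not in markers:
        raise ValueError(f"reference marker {reference!r} not among markers")
    vat = np.array([np.nan if r.ct_vat is None else r.ct_vat for r in cohort], dtype=float)
    if np.isnan(vat).any():
        raise VatPredictError("every record needs a measured ct_vat")
    outcome = rule(vat).astype(int)
    sex = np.array([r.sex for r in cohort])
    strata = (("male", sex == "male"), ("female", sex == "female")) if stratify_by_sex \
        else (("all", np.ones(len(cohort), dtype=bool)),)

    rows = []
    for name, mask in strata:
        y = outcome[mask]
        if np.unique(y).size < 2 or mask.sum() == 0:
            rows.append({"stratum": name, "marker": None, "auc": np.nan, "se": np.nan,
                         "p_vs_reference": np.nan,
                         "note": "stratum skipped: single outcome class"})
            continue
        ref_scores = np.asarray(markers[reference], dtype=float)[mask]
        for marker, scores in markers.items():
            s = np.asarray(scores, dtype=float)[mask]
            r = roc(s, y)
            if marker == reference:
                p = np.nan
            else:
                p = delong_paired_test(ref_scores, s, y).p
            rows.append({"stratum": name, "marker": marker, "auc": r.auc,
                         "se": r.se, "p_vs_reference": p, "note": ""})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GofReport:
    """Regression goodness-of-fit battery (e = observed − predicted).

    rmse    sqrt(mean e²), response units
    rrmse   100·rmse/mean(obs), %
    sdr     sd(e)/sd(obs)
    cv      100·sd(e)/mean(obs), %
    pc      Pearson correlation of observed and predicted
    pi      rrmse/(1 + pc)
    me      mean(e)
    rae     Σe²/Σobs²
    mrae    mean(|e|/obs)
    mape    100·mean(|e|/obs), %
    mad     mean(|e|)
    aic     n·ln(Σe²/n) + 2p
    caic    aic + 2p(p+1)/(n−p−1)
    """

    rmse: float
    rrmse: float
    sdr: float
    cv: float
    pc: float
    pi: float
    me: float
    rae: float
    mrae: float
    mape: float
    mad: float
    aic: float
    caic: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rmse", "rrmse", "sdr", "cv", "pc", "pi", "me", "rae",
                 "mrae", "mape", "mad", "aic", "caic")}


def gof(observed, predicted, n_params: int = 1) -> GofReport:
    """Goodness-of-fit report; ``n_params`` is the effective parameter
    count (terms including the constant) used by AIC/CAIC."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")
    n = obs.size
    e = obs - pred
    sse = float(np.sum(e ** 2))
    rmse = float(np.sqrt(sse / n))
    mean_obs = float(obs.mean())
    if mean_obs <= 0:
        raise DomainError("ratio measures need mean(observed) > 0")
    sd_obs = float(obs.std(ddof=1))
    sd_e = float(e.std(ddof=1))
    if np.allclose(pred, pred[0]) or sd_obs == 0:
        pc = np.nan
    else:
        pc = float(np.corrcoef(obs, pred)[0, 1])
    rrmse = 100.0 * rmse / mean_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(e) / obs
    rel_ok = np.isfinite(rel)
    mape = float(100.0 * rel[rel_ok].mean()) if rel_ok.any() else np.nan
    mrae = float(rel[rel_ok].mean()) if rel_ok.any() else np.nan
    p = int(n_params)
    aic = float(n * np.log(sse / n) + 2 * p) if sse > 0 else -np.inf
    caic = aic + 2.0 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else np.inf
    return GofReport(
        rmse=rmse, rrmse=rrmse,
        sdr=sd_e / sd_obs if sd_obs > 0 else np.nan,
        cv=100.0 * sd_e / mean_obs,
        pc=pc,
        pi=rrmse / (1.0 + pc) if np.isfinite(pc) else np.nan,
        me=float(e.mean()),
        rae=sse / float(np.sum(obs ** 2)),
        mrae=mrae, mape=mape, mad=float(np.abs(e).mean()),
        aic=aic, caic=caic,
    )


@dataclass(frozen=True)
class CalibrationReport:
    """Calibration of predictions against observations.

    ``citl_mean_diff`` is mean(observed) − mean(predicted) (calibration
    in the large as a systematic offset); ``citl_intercept`` and
    ``slope`` come from the OLS fit observed = a + b·predicted, and
    ``rsq`` is its R².  Perfect predictions give slope 1, offset 0, R² 1.
    """

    citl_mean_diff: float
    citl_intercept: float
    slope: float
    rsq: float


def calibration(observed, predicted) -> CalibrationReport:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(pred, pred[0]):
        raise DomainError("calibration slope undefined for constant predictions")
    res = stats.linregress(pred, obs)
    return CalibrationReport(
        citl_mean_diff=float(obs.mean() - pred.mean()),
        citl_intercept=float(res.intercept),
        slope=float(res.slope),
        rsq=float(res.rvalue ** 2),
    )
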