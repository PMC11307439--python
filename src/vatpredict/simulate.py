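"""Synthetic cohorts with the study group's gender-stratified structure.

Subjects are drawn per sex from a correlated multivariate normal over
age, height, waist/hip circumference, BMI, blood pressures, glucose,
triglycerides, HDL and c-peptide, truncated to physiological bounds by
resampling.  Because box truncation would bias the means of skew-bound
variables (triglycerides most of all), each latent univariate mean is
calibrated so that the *truncated* marginal hits the profile's target
mean exactly.  Weight is derived from BMI and height, and "measured"
VAT is the published anthropometric model's prediction plus Gaussian
noise (default SD 41 cm², the published residual scale), floored at
1 cm².  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, SubjectRecord
from .errors import VatPredictError
from .model import predict_vat_batch, published_vat_model

__all__ = ["SyntheticProfile", "GeneratorSpec", "default_profile",
           "generate", "generate_fit_dataset", "CONTINUOUS_VARIABLES",
           "CANDIDATE_PREDICTORS"]

CONTINUOUS_VARIABLES = ("age", "height", "wc", "hc", "bmi", "sbp", "dbp",
                        "glucose", "tg", "hdl", "c_peptide")

#: the nine candidate predictors of the modelling workflow, in order
CANDIDATE_PREDICTORS = ("age", "sex", "wc", "hc", "bmi", "glucose",
                        "c_peptide", "tg", "hdl")

# study-group gender-stratified means and SDs (age..hdl from the study
# group descriptives; height and c-peptide are not tabulated there and
# use typical adult values for the study population)
_MALE_STATS = {
    "age": (39.6, 7.3), "height": (173.0, 7.0), "wc": (93.6, 10.9),
    "hc": (103.4, 7.6), "bmi": (26.5, 4.2), "sbp": (122.3, 15.5),
    "dbp": (80.0, 9.4), "glucose": (88.6, 10.7), "tg": (131.8, 70.5),
    "hdl": (45.4, 10.9), "c_peptide": (2.0, 0.8),
}
_FEMALE_STATS = {
    "age": (37.3, 8.3), "height": (160.0, 6.5), "wc": (86.6, 15.5),
    "hc": (104.5, 13.3), "bmi": (27.0, 6.5), "sbp": (111.6, 12.0),
    "dbp": (79.9, 9.0), "glucose": (90.4, 11.8), "tg": (101.4, 62.3),
    "hdl": (55.3, 13.5), "c_peptide": (2.0, 0.8),
}

# typical cardiometabolic-cohort correlation magnitudes; default 0.10
_CORR_OVERRIDES = {
    ("wc", "bmi"): 0.85, ("wc", "hc"): 0.80, ("bmi", "hc"): 0.80,
    ("wc", "tg"): 0.35, ("wc", "glucose"): 0.30, ("wc", "hdl"): -0.30,
    ("tg", "hdl"): -0.40, ("age", "wc"): 0.20, ("c_peptide", "bmi"): 0.40,
}
_DEFAULT_CORR = 0.10

# physiological truncation bounds; resampling, not clipping
_BOUNDS = {
    "age": (20.0, 50.0), "height": (140.0, 210.0), "wc": (55.0, 160.0),
    "hc": (70.0, 180.0), "bmi": (15.0, 60.0), "sbp": (80.0, 220.0),
    "dbp": (40.0, 130.0), "glucose": (60.0, 125.0), "tg": (30.0, 600.0),
    "hdl": (20.0, 120.0), "c_peptide": (0.2, 8.0),
}

#: variables nudged upward (dysmetabolism) / downward by the shift dial
_SHIFT_UP = ("wc", "tg", "glucose", "sbp", "dbp")
_SHIFT_DOWN = ("hdl",)


def _build_correlation(overrides: Mapping) -> np.ndarray:
    k = len(CONTINUOUS_VARIABLES)
    pos = {v: i for i, v in enumerate(CONTINUOUS_VARIABLES)}
    corr = np.full((k, k), _DEFAULT_CORR)
    np.fill_diagonal(corr, 1.0)
    for (a, b), rho in overrides.items():
        corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = rho
    return _nearest_psd_correlation(corr)


def _nearest_psd_correlation(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalization to unit diagonal."""
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    vals = np.clip(vals, floor, None)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


@dataclass(frozen=True)
class SyntheticProfile:
    """Per-sex moments, shared correlation structure and noise settings."""

    male: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_MALE_STATS))
    female: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_FEMALE_STATS))
    correlation_overrides: Mapping = field(
        default_factory=lambda: dict(_CORR_OVERRIDES))
    sex_fraction_female: float = 0.584
    vat_noise_sd: float = 41.0
    dysmetabolism_shift: float = 0.0
    tg_lognormal: bool = False
    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_BOUNDS))

    def __post_init__(self):
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        if self.vat_noise_sd < 0:
            raise ValueError("vat_noise_sd must be >= 0")
        for sex_stats in (self.male, self.female):
            for v in CONTINUOUS_VARIABLES:
                if v not in sex_stats:
                    raise ValueError(f"profile misses variable {v!r}")
                if sex_stats[v][1] <= 0:
                    raise ValueError(f"SD of {v!r} must be positive")
        # raises early on structurally invalid correlation input
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        corr = _build_correlation(self.correlation_overrides)
        if not np.allclose(corr, corr.T) or (np.abs(corr) > 1 + 1e-9).any():
            raise VatPredictError("invalid correlation matrix")
        return corr

    def stats_for(self, sex: str) -> Mapping[str, Tuple[float, float]]:
        base = self.male if sex == "male" else self.female
        if self.dysmetabolism_shift == 0:
            return dict(base)
        shifted = {}
        for v, (m, s) in base.items():
            if v in _SHIFT_UP:
                m = m + self.dysmetabolism_shift * s
            elif v in _SHIFT_DOWN:
                m = m - self.dysmetabolism_shift * s
            shifted[v] = (m, s)
        return shifted


@dataclass(frozen=True)
class GeneratorSpec:
    profile: SyntheticProfile
    n: int
    seed: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")


def default_profile() -> SyntheticProfile:
    """Profile transcribing the study group's gender-stratified values."""
    return SyntheticProfile()


def _latent_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose (lo, hi)-truncated mean equals *target*."""

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd)

    shift0 = trunc_mean(target) - target
    if abs(shift0) < 1e-12:
        return target
    lo_b, hi_b = target - 8.0 * sd, target + 8.0 * sd
    return optimize.brentq(lambda mu: trunc_mean(mu) - target, lo_b, hi_b,
                           xtol=1e-10)


#: internal seed of the latent-mean calibration draw; independent of the
#: user's generation seed so calibration is a fixed property of a profile.
_CALIBRATION_SEED = 987654321
_CALIBRATION_DRAWS = 480_000

#: memo of calibrated latent means keyed by the profile block contents
_CALIBRATION_CACHE: dict = {}


def _calibrate_latent_means(targets: np.ndarray, sds: np.ndarray,
                            lo: np.ndarray, hi: np.ndarray,
                            chol: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Latent means whose box-truncated joint mean hits the targets.

    Box truncation biases a variable both through its own bounds and,
    via correlation, through its neighbours' bounds (rejecting low-BMI
    rows also rejects low-WC rows), so no univariate correction
    suffices.  This solves the joint problem empirically: one fixed
    common-random-numbers draw of the latent multivariate normal is
    reused while the mean vector is iteratively shifted by the measured
    post-truncation bias.  With common random numbers the iteration
    converges to the sample-exact fixed point; the residual bias is the
    sampling error of the calibration draw, ~0.3% of an SD.
    """
    key = (targets.tobytes(), sds.tobytes(), lo.tobytes(), hi.tobytes(),
           chol.tobytes())
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    mu = np.array([_latent_mean(t, s, l, h)
                   for t, s, l, h in zip(targets, sds, lo, hi)])
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.standard_normal((_CALIBRATION_DRAWS, targets.size)) @ chol.T
    for _ in range(n_iter):
        x = z + mu
        acc = ((x >= lo) & (x <= hi)).all(axis=1)
        if not acc.any():
            raise VatPredictError("calibration draw has empty acceptance region")
        bias = x[acc].mean(axis=0) - targets
        if np.max(np.abs(bias) / sds) < 1e-4:
            break
        mu = mu - bias
    _CALIBRATION_CACHE[key] = mu
    return mu


def _draw_sex_block(rng: np.random.Generator, n: int, sex: str,
                    profile: SyntheticProfile) -> pd.DataFrame:
    sex_stats = profile.stats_for(sex)
    corr = profile.correlation_matrix()
    vars_ = CONTINUOUS_VARIABLES
    sds = np.array([sex_stats[v][1] for v in vars_])
    lo = np.array([profile.bounds[v][0] for v in vars_])
    hi = np.array([profile.bounds[v][1] for v in vars_])
    targets = np.array([sex_stats[v][0] for v in vars_])
    cov = corr * np.outer(sds, sds)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(vars_)))
    mu = _calibrate_latent_means(targets, sds, lo, hi, chol)

    def draw(k):
        z = rng.standard_normal((k, len(vars_)))
        return z @ chol.T + mu

    block = draw(n)
    for _ in range(1000):
        bad = ((block < lo) | (block > hi)).any(axis=1)
        if not bad.any():
            break
        block[bad] = draw(int(bad.sum()))
    else:
        raise VatPredictError("truncation resampling did not converge")
    df = pd.DataFrame(block, columns=list(vars_))
    if profile.tg_lognormal:
        # Gaussian-copula lognormal marginal, moment-matched to (mean, sd)
        m, s = sex_stats["tg"]
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu_ln = math.log(m) - sigma2 / 2.0
        z = (df["tg"] - mu[vars_.index("tg")]) / sds[vars_.index("tg")]
        df["tg"] = np.exp(mu_ln + math.sqrt(sigma2) * z)
        df["tg"] = df["tg"].clip(*profile.bounds["tg"])
    df.insert(0, "sex", sex)
    return df


def generate(spec: GeneratorSpec) -> Cohort:
    """Generate a cohort; identical specs give bit-identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    profile = spec.profile
    is_female = rng.random(spec.n) < profile.sex_fraction_female
    n_f = int(is_female.sum())
    n_m = spec.n - n_f
    blocks = []
    if n_m:
        blocks.append(_draw_sex_block(rng, n_m, "male", profile))
    if n_f:
        blocks.append(_draw_sex_block(rng, n_f, "female", profile))
    df = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    # interleave back into the drawn sex order
    order = np.empty(spec.n, dtype=int)
    order[~is_female] = np.arange(n_m)
    order[is_female] = n_m + np.arange(n_f)
    df = df.iloc[order].reset_index(drop=True)
    df["weight"] = df["bmi"] * (df["height"] / 100.0) ** 2

    records = []
    for i, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=f"S{i:06d}", sex=row["sex"], age=float(row["age"]),
            height=float(row["height"]), weight=float(row["weight"]),
            wc=float(row["wc"]), hc=float(row["hc"]), sbp=float(row["sbp"]),
            dbp=float(row["dbp"]), glucose=float(row["glucose"]),
            tg=float(row["tg"]), hdl=float(row["hdl"]),
            c_peptide=float(row["c_peptide"])))
    cohort = Cohort(records=records, label=f"synthetic(seed={spec.seed}, n={spec.n})")

    model = published_vat_model()
    preds, _ = predict_vat_batch(model, cohort)
    noise = rng.normal(0.0, profile.vat_noise_sd, spec.n) if profile.vat_noise_sd > 0 \
        else np.zeros(spec.n)
    vat = np.maximum(1.0, preds.to_numpy() + noise)
    cohort = Cohort(records=[r.replace(ct_vat=float(v))
                             for r, v in zip(records, vat)],
                    label=cohort.label)
    return cohort


def generate_fit_dataset(spec: GeneratorSpec):
    """(X, y) with exactly the nine candidate predictors of the modelling
    workflow — age, sex, WC, HC, BMI, glucose, c-peptide, TG, HDL — and
    the simulated measured VAT as response."""
    cohort = generate(spec)
    frame = cohort.to_frame()
    X = frame[list(CANDIDATE_PREDICTORS)].copy()
    y = frame["ct_vat"].to_numpy()
    return X, y
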