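"""MARS fitting: forward hinge selection, GCV pruning, importance, CV.

The forward pass greedily grows a basis of hinge pairs
``max(0, x − t) / max(0, t − x)`` (added jointly) and categorical
indicators, optionally multiplied onto an existing degree-1 term
(first-order interactions).  Candidate knots are observed data values.
The backward pass deletes terms one at a time — possibly one member of
a hinge pair — choosing at each step the deletion with the lowest
generalized cross-validation score

    GCV = (RSS/n) / (1 − C(M)/n)²,   C(M) = (k+1) + penalty·k

for k basis terms plus the constant, and returns the GCV-minimal model
along the deletion path.  Variable importance is the summed GCV
increase attributed to each variable over the full deletion sequence,
normalized so the top variable scores 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FitError
from .model import BasisFunction, HingeFactor, IndicatorFactor, MarsModel

__all__ = ["FitConfig", "FitResult", "forward_pass", "gcv_score",
           "backward_prune", "fit_mars", "variable_importance", "kfold_cv"]

_EPS = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the MARS engine.

    max_basis_functions : forward-pass budget of basis terms (a hinge
        pair consumes two), excluding the constant.
    max_degree : 1 for additive models, 2 to allow first-order
        interactions (the default and the maximum supported).
    gcv_penalty : cost per knot in the GCV effective-parameter count;
        3 is the conventional value for interaction-permitting MARS.
    min_span : minimum observations between consecutive candidate knots.
    endspan : observations excluded at each end of a predictor's range
        before knots are eligible — the classical guard against hinges
        chasing noise on a handful of extreme points.  ``None`` (the
        default) uses the standard automatic value
        ``int(3 − log2(0.05/d))`` for d predictors; 0 disables it.
    max_knots_per_predictor : quantile-thins the candidate knots of a
        predictor to at most this many observed values, bounding the
        forward-pass search at large n (no effect when the predictor
        has fewer distinct values).
    forward_tolerance : stop the forward pass when the best candidate's
        relative RSS improvement falls below this.
    seed : reserved for randomized tie-breaking; selection is currently
        fully deterministic, so it only enters the trace.
    """

    max_basis_functions: int = 20
    max_degree: int = 2
    gcv_penalty: float = 3.0
    min_span: int = 1
    endspan: Optional[int] = None
    max_knots_per_predictor: int = 128
    forward_tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.max_basis_functions < 1:
            raise ValueError("max_basis_functions must be >= 1")
        if self.max_degree not in (1, 2):
            raise ValueError("max_degree must be 1 or 2")
        if self.gcv_penalty < 0:
            raise ValueError("gcv_penalty must be >= 0")
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")
        if self.endspan is not None and self.endspan < 0:
            raise ValueError("endspan must be >= 0")

    def resolved_endspan(self, n_predictors: int) -> int:
        if self.endspan is not None:
            return self.endspan
        return int(3 - math.log2(0.05 / max(1, n_predictors)))


@dataclass
class FitResult:
    model: MarsModel
    gcv: float
    rsq: float
    importance: list  # [(variable, score)] descending, max normalized to 100
    trace: list       # per-step log dicts from both phases


# ---------------------------------------------------------------------------
# helpers

def _is_categorical(col: pd.Series) -> bool:
    return (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool)


def _candidate_knots(x: np.ndarray, min_span: int, max_knots: int,
                     endspan: int = 0) -> np.ndarray:
    """Observed-value candidate knots honoring min_span and endspan,
    quantile-thinned to at most max_knots."""
    xs = np.sort(x)
    if endspan > 0:
        if xs.size <= 2 * endspan:
            return np.empty(0)
        xs = xs[endspan:xs.size - endspan]
    uniq, first_idx = np.unique(xs, return_index=True)
    if min_span > 1:
        kept, last_pos = [], -min_span
        for v, pos in zip(uniq, first_idx):
            if pos - last_pos >= min_span:
                kept.append(v)
                last_pos = pos
        uniq = np.asarray(kept)
    if uniq.size > max_knots:
        sel = np.unique(np.linspace(0, uniq.size - 1, max_knots).round().astype(int))
        uniq = uniq[sel]
    return uniq


def _term_column(factors: tuple, X: pd.DataFrame) -> np.ndarray:
    col = np.ones(len(X))
    for f in factors:
        col = col * np.asarray(f(X[f.variable].to_numpy()), dtype=float)
    return col


def _design(terms: Sequence[tuple], X: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(X))]
    cols.extend(_term_column(t, X) for t in terms)
    return np.column_stack(cols)


def _lstsq(B: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ beta
    return beta, float(resid @ resid)


def _terms_to_model(terms: Sequence[tuple], X: pd.DataFrame, y: np.ndarray,
                    response_name: str) -> Tuple[MarsModel, float]:
    B = _design(terms, X)
    beta, rss = _lstsq(B, y)
    bfs = tuple(BasisFunction(float(b), t) for b, t in zip(beta[1:], terms))
    return MarsModel(constant=float(beta[0]), basis_functions=bfs,
                     response_name=response_name), rss


def _model_terms(model: MarsModel) -> list:
    return [bf.factors for bf in model.basis_functions]


def _effective_params(n_terms: int, penalty: float) -> float:
    return (n_terms + 1) + penalty * n_terms


def _gcv_from_rss(rss: float, n: int, n_terms: int, penalty: float) -> float:
    c = _effective_params(n_terms, penalty)
    if c >= n:
        return math.inf
    return (rss / n) / (1.0 - c / n) ** 2


# ---------------------------------------------------------------------------
# forward pass

def forward_pass(X: pd.DataFrame, y, config: FitConfig = FitConfig(),
                 response_name: str = "y") -> MarsModel:
    """Greedy basis growth; returns the (deliberately overfit) candidate.

    At each step every (parent term × hinge pair at a candidate knot)
    and (parent × categorical indicator) is scored by its residual
    sum-of-squares reduction; hinge pairs enter jointly.  Ties break to
    the smallest knot, then predictor order as supplied, then parent
    order.  Stops at the term budget or when the best relative RSS
    improvement drops below ``forward_tolerance``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise FitError(f"need at least 10 observations, got {n}")
    if not np.isfinite(y).all():
        raise FitError("response contains non-finite values")
    for c in X.columns:
        if not _is_categorical(X[c]) and not np.isfinite(X[c].to_numpy(dtype=float)).all():
            raise FitError(f"predictor {c!r} contains missing/non-finite values")

    numeric_cols = [c for c in X.columns if not _is_categorical(X[c])]
    cat_cols = [c for c in X.columns if _is_categorical(X[c])]
    endspan = config.resolved_endspan(len(X.columns))
    knots = {c: _candidate_knots(X[c].to_numpy(dtype=float), config.min_span,
                                 config.max_knots_per_predictor, endspan)
             for c in numeric_cols}
    # reference level = last alphabetically; indicators for the rest
    # (for sex this makes "male" the reference and "female" the indicator,
    # the convention of the published model)
    cat_levels = {c: sorted(map(str, pd.unique(X[c].astype(str))))[:-1] for c in cat_cols}
    xcache = {c: X[c].to_numpy(dtype=float) for c in numeric_cols}
    catcache = {c: X[c].astype(str).to_numpy() for c in cat_cols}

    terms: List[tuple] = []
    trace = []
    B = np.ones((n, 1))
    Q, _ = np.linalg.qr(B)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)

    while len(terms) < config.max_basis_functions:
        if rss <= _EPS * max(1.0, float(y @ y)):
            break
        slots = config.max_basis_functions - len(terms)
        parents = [None] + [i for i, t in enumerate(terms) if len(t) < config.max_degree]
        best = None  # (key, new_factor_tuples, descriptor)

        for p_idx, parent in enumerate(parents):
            if parent is None:
                pb = np.ones(n)
                parent_factors = ()
            else:
                pb = B[:, parent + 1]
                parent_factors = terms[parent]
            used_vars = {f.variable for f in parent_factors}

            for v_idx, var in enumerate(X.columns):
                if var in used_vars:
                    continue
                if var in cat_cols:
                    for level in cat_levels[var]:
                        c = pb * (catcache[var] == level)
                        a = Q.T @ c
                        s = float(c @ c - a @ a)
                        if s <= _EPS * max(1.0, float(c @ c)):
                            continue
                        red = float(c @ r) ** 2 / s
                        key = (-red, math.inf, v_idx, p_idx)
                        cand = [parent_factors + (IndicatorFactor(var, level),)]
                        if red > 0 and (best is None or key < best[0]):
                            best = (key, cand, {"variable": var, "level": level,
                                                "parent": parent_factors})
                    continue

                x = xcache[var]
                t = knots[var]
                if t.size == 0:
                    continue
                pbx = pb * x
                C1 = np.maximum(0.0, x[:, None] - t[None, :]) * pb[:, None]  # above
                A1 = Q.T @ C1
                n11 = np.einsum("ij,ij->j", C1, C1) - np.einsum("ij,ij->j", A1, A1)
                u1 = C1.T @ r
                # below-hinge column c2 = c1 − (pbx − t·pb): derive its stats
                qpb = Q.T @ pb
                qpbx = Q.T @ pbx
                A2 = A1 - (qpbx[:, None] - np.outer(qpb, t))
                u2 = u1 - (float(pbx @ r) - t * float(pb @ r))
                c1_pbx = C1.T @ pbx
                c1_pb = C1.T @ pb
                pbx2 = float(pbx @ pbx)
                pbxpb = float(pbx @ pb)
                pb2 = float(pb @ pb)
                raw22 = (np.einsum("ij,ij->j", C1, C1)
                         - 2.0 * (c1_pbx - t * c1_pb)
                         + (pbx2 - 2.0 * t * pbxpb + t * t * pb2))
                n22 = raw22 - np.einsum("ij,ij->j", A2, A2)
                raw12 = np.einsum("ij,ij->j", C1, C1) - (c1_pbx - t * c1_pb)
                n12 = raw12 - np.einsum("ij,ij->j", A1, A2)

                scale1 = np.maximum(1.0, np.einsum("ij,ij->j", C1, C1))
                scale2 = np.maximum(1.0, raw22)
                ok1 = n11 > _EPS * scale1
                ok2 = n22 > _EPS * scale2
                det = n11 * n22 - n12 ** 2
                okp = ok1 & ok2 & (det > _EPS * scale1 * scale2) & (slots >= 2)
                with np.errstate(divide="ignore", invalid="ignore"):
                    red_pair = np.where(
                        okp, (n22 * u1 ** 2 - 2.0 * n12 * u1 * u2 + n11 * u2 ** 2)
                        / np.where(okp, det, 1.0), -np.inf)
                    red1 = np.where(ok1, u1 ** 2 / np.where(ok1, n11, 1.0), -np.inf)
                    red2 = np.where(ok2, u2 ** 2 / np.where(ok2, n22, 1.0), -np.inf)

                option_dirs = (("above", "below"), ("above",), ("below",))
                stacked = np.vstack([red_pair, red1, red2])
                if slots < 2:
                    stacked[0, :] = -np.inf
                choice = np.argmax(stacked, axis=0)  # tie prefers the joint pair
                per_knot = stacked[choice, np.arange(t.size)]
                if not np.any(per_knot > 0):
                    continue
                k_idx = int(np.argmax(per_knot))  # tie -> smallest knot (t ascending)
                red = float(per_knot[k_idx])
                dirs = option_dirs[choice[k_idx]]
                key = (-red, float(t[k_idx]), v_idx, p_idx)
                if best is None or key < best[0]:
                    cand = [parent_factors + (HingeFactor(var, float(t[k_idx]), d),)
                            for d in dirs]
                    best = (key, cand, {"variable": var, "knot": float(t[k_idx]),
                                        "directions": dirs, "parent": parent_factors})

        if best is None:
            break
        red = -best[0][0]
        if red / rss < config.forward_tolerance:
            break
        new_terms = best[1]
        trial = terms + new_terms
        B_trial = _design(trial, X)
        Q_trial, _ = np.linalg.qr(B_trial)
        r_trial = y - Q_trial @ (Q_trial.T @ y)
        rss_trial = float(r_trial @ r_trial)
        if rss - rss_trial <= 0:
            break
        terms, B, Q, r = trial, B_trial, Q_trial, r_trial
        trace.append({"phase": "forward", "action": "add", "rss": rss_trial,
                      "rss_reduction": rss - rss_trial,
                      "n_terms": len(terms), **best[2]})
        rss = rss_trial

    model, _ = _terms_to_model(terms, X, y, response_name)
    model = replace(model)
    object.__setattr__(model, "_trace", trace)  # carried into fit_mars
    return model


# ---------------------------------------------------------------------------
# GCV and backward pruning

def gcv_score(model: MarsModel, X: pd.DataFrame, y, penalty: float = 3.0) -> float:
    """Generalized cross-validation score of *model* refit on (X, y).

    Returns +inf when the effective parameter count reaches n.
    """
    y = np.asarray(y, dtype=float)
    terms = _model_terms(model)
    _, rss = _terms_to_model(terms, X, y, model.response_name)
    return _gcv_from_rss(rss, len(y), len(terms), penalty)


def backward_prune(candidate: MarsModel, X: pd.DataFrame, y,
                   config: FitConfig = FitConfig()) -> FitResult:
    """GCV-driven backward deletion.

    Deletes, at each step, the term whose removal gives the lowest GCV
    (coefficients re-estimated by least squares each time), continues to
    the constant-only model, and returns the GCV-minimal model over the
    whole deletion path.  The per-deletion GCV increases feed variable
    importance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    current = _model_terms(candidate)
    trace = list(getattr(candidate, "_trace", []))

    def _score(terms):
        model, rss = _terms_to_model(terms, X, y, candidate.response_name)
        return model, rss, _gcv_from_rss(rss, n, len(terms), config.gcv_penalty)

    model_full, rss_full, gcv_full = _score(current)
    best_terms, best_gcv = list(current), gcv_full
    deletions = []  # (removed_term, gcv_before, gcv_after)
    gcv_now = gcv_full
    while current:
        choices = []
        for i in range(len(current)):
            sub = current[:i] + current[i + 1:]
            _, rss_i = _terms_to_model(sub, X, y, candidate.response_name)
            choices.append((_gcv_from_rss(rss_i, n, len(sub), config.gcv_penalty), i))
        gcv_next, drop = min(choices)
        removed = current[drop]
        deletions.append((removed, gcv_now, gcv_next))
        trace.append({"phase": "backward", "action": "delete",
                      "term": [f.to_dict() for f in removed],
                      "gcv_before": gcv_now, "gcv_after": gcv_next,
                      "n_terms": len(current) - 1})
        current = current[:drop] + current[drop + 1:]
        gcv_now = gcv_next
        if gcv_next < best_gcv:
            best_gcv, best_terms = gcv_next, list(current)

    final_model, rss_final = _terms_to_model(best_terms, X, y, candidate.response_name)
    sst = float(np.sum((y - y.mean()) ** 2))
    rsq = 1.0 - rss_final / sst if sst > 0 else 0.0
    rsq = min(max(rsq, 0.0), 1.0)

    forward_steps = [e for e in trace if e.get("phase") == "forward"]
    if forward_steps:
        importance = _importance_from_forward(forward_steps, final_model)
    else:
        importance = _importance_from_deletions(deletions, final_model)
    return FitResult(model=final_model, gcv=best_gcv, rsq=rsq,
                     importance=importance, trace=trace)


def _importance_from_forward(steps, final_model: MarsModel) -> list:
    """Entry-order importance: the RSS reduction achieved when each
    variable's terms entered in the forward pass, summed per variable.

    Attributing credit at entry rather than along the deletion path
    keeps strongly collinear predictors from trading credit: the
    variable that carries the signal gets it.
    """
    raw: Dict[str, float] = {}
    for e in steps:
        raw[e["variable"]] = raw.get(e["variable"], 0.0) + e.get("rss_reduction", 0.0)
    keep = set(final_model.variables)
    raw = {v: s for v, s in raw.items() if v in keep}
    if not raw:
        return []
    top = max(raw.values())
    scored = [(v, 100.0 * s / top if top > 0 else 0.0) for v, s in raw.items()]
    return sorted(scored, key=lambda vs: (-vs[1], vs[0]))


def _importance_from_deletions(deletions, final_model: MarsModel) -> list:
    raw: Dict[str, float] = {}
    for removed, before, after in deletions:
        if not (math.isfinite(before) and math.isfinite(after)):
            continue
        delta = max(after - before, 0.0)
        for f in removed:
            raw[f.variable] = raw.get(f.variable, 0.0) + delta
    keep = set(final_model.variables)
    raw = {v: s for v, s in raw.items() if v in keep}
    if not raw:
        return []
    top = max(raw.values())
    if top <= 0:
        scored = [(v, 0.0) for v in raw]
    else:
        scored = [(v, 100.0 * s / top) for v, s in raw.items()]
    # descending score, ties alphabetical
    return sorted(scored, key=lambda vs: (-vs[1], vs[0]))


def fit_mars(X: pd.DataFrame, y, config: FitConfig = FitConfig(),
             response_name: str = "y") -> FitResult:
    """Forward pass then backward pruning; deterministic given inputs."""
    candidate = forward_pass(X, y, config, response_name=response_name)
    return backward_prune(candidate, X, y, config)


def variable_importance(result: FitResult, X: Optional[pd.DataFrame] = None,
                        y=None) -> list:
    """Ranked (variable, score) list, max normalized to 100.

    The ranking is computed during pruning and stored on the result;
    passing (X, y) is accepted for signature compatibility and triggers
    a recomputation via a fresh prune when the stored ranking is absent.
    """
    if result.importance is not None:
        return result.importance
    if X is None or y is None:
        raise ValueError("result carries no importance; supply X and y")
    return backward_prune(result.model, X, y).importance


def kfold_cv(X: pd.DataFrame, y, config: FitConfig = FitConfig(),
             k: int = 10, seed: int = 0) -> dict:
    """Seeded k-fold cross-validation of the full fit pipeline.

    Folds are formed by shuffling indices with the seed and splitting
    contiguously.  Returns per-fold and pooled out-of-fold R² and RMSE.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k observations (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    oof = np.full(n, np.nan)
    per_fold = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        res = fit_mars(X.iloc[train_idx].reset_index(drop=True), y[train_idx], config)
        pred = res.model.predict_table(X.iloc[test_idx].reset_index(drop=True))
        oof[test_idx] = pred
        e = y[test_idx] - pred
        sst = float(np.sum((y[test_idx] - y[test_idx].mean()) ** 2))
        per_fold.append({
            "fold": i, "n": int(test_idx.size),
            "rmse": float(np.sqrt(np.mean(e ** 2))),
            "rsq": 1.0 - float(np.sum(e ** 2)) / sst if sst > 0 else np.nan,
        })
    e = y - oof
    sst = float(np.sum((y - y.mean()) ** 2))
    pooled = {"rmse": float(np.sqrt(np.mean(e ** 2))),
              "rsq": 1.0 - float(np.sum(e ** 2)) / sst if sst > 0 else np.nan}
    return {"per_fold": per_fold, "pooled": pooled,
            "fold_assignment": [sorted(map(int, f)) for f in folds]}
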