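# Methods

## The prediction model

The core object is a MARS (multivariate adaptive regression splines)
model: an intercept plus basis functions, each a coefficient multiplied
by one or two factors, where a factor is either a hinge
max(0, x − t) / max(0, t − x) on a continuous predictor or an indicator
on a categorical one. Degree is capped at 2 (first-order interactions),
and no variable may appear twice within one term, so every model is
continuous and piecewise linear in each continuous predictor.

The packaged published model predicts CT-measured VAT area (cm²) from
sex, waist circumference, hip circumference and BMI (constant 249 plus
seven basis functions; see the README for the full expression). Two
details of its interpretation deserve note, because the flattened
one-line equation sometimes quoted for such models drops conditions
that the tabulated basis-function form carries:

- the +7.18·(29 − BMI)₊ term applies to women only;
- the 0.459 interaction is a product of two hinges, active only when
  both WC < 111 and BMI < 28.4.

We implement the tabulated semantics. They are the only reading under
which the prediction for a man at WC 111 / HC 106 / BMI 25.9 equals the
constant — a property we pin in tests. Hinges make the "<" vs "≤"
boundary question immaterial: both sides of each knot agree at the knot.

BMI is derived from height and weight when both are present; an
explicitly supplied `bmi` column is honored otherwise. If both exist
and disagree by more than 0.1 kg/m², a warning is emitted and the
computed value wins. Predictions outside 0–700 cm² trigger a
plausibility warning (physiological limits for an L3-slice area) but
are returned unchanged — the model has no extrapolation guard.

## Units

Storage is canonical throughout: lengths in cm, weight in kg, pressures
in mmHg, glucose and lipids in mg/dl. Index formulas convert
internally: triglycerides mg/dl → mmol/l by 88.57, cholesterol by 38.67
(molecular-weight constants; overridable). ABSI uses metres for both
waist and height, the convention that yields the familiar ~0.08
magnitude. METS-IR follows the original definition
ln(2·glucose + TG)·BMI / ln(HDL) with everything in mg/dl; METS-VF
consumes ln-cubed METS-IR and waist-to-height ratio with a +0.319 male
offset. LAP may be negative when the waist is below its sex anchor
(65 cm men / 58 cm women); it is returned negative and flagged rather
than truncated.

## The fitting engine

`fit.forward_pass` grows the basis greedily. At each step every
candidate move — a parent term (the intercept or any degree-1 term)
times a hinge pair at a candidate knot, or times a categorical
indicator — is scored by its exact least-squares RSS reduction,
computed for all knots of a predictor at once from the QR factorization
of the current design (the below-hinge column's statistics follow from
the above-hinge's by the identity c₋ = c₊ − parent·(x − t), so only one
n×K matrix product per (parent, predictor) pair is needed). Hinge pairs
enter jointly; ties break to the smaller knot, then predictor order,
then parent order, making the pass fully deterministic. The pass stops
at the term budget (default 20, matching the derivation workflow's
candidate count) or when the best relative RSS improvement falls below
`forward_tolerance` (default 1e-4).

Candidate knots are observed data values, filtered three ways:

- `min_span` (default 1): minimum observations between consecutive
  knots;
- `endspan` (default automatic, int(3 − log2(0.05/d)) ≈ 10 for d = 9
  predictors): the classical guard excluding knots within a few
  observations of a predictor's extremes, where hinges on a handful of
  points chase noise;
- `max_knots_per_predictor` (default 128): quantile thinning that
  bounds the search at large n. At n ≤ 128 every observed value remains
  a candidate, so small-sample behavior is exact.

`fit.backward_prune` deletes one term at a time — possibly one member
of a hinge pair, which is how unpaired terms arise in final models —
always choosing the deletion with the lowest generalized
cross-validation score

    GCV = (RSS/n) / (1 − C/n)²,   C = (k+1) + penalty·k

for k basis terms, refitting coefficients by least squares at each
step, and returns the GCV-minimal model along the deletion path. The
penalty default is 3, the conventional value for interaction-permitting
MARS. GCV-based pruning is one canonical choice; significance-based
backward elimination is a near-equivalent alternative we did not adopt.

### Variable importance

Importance is reported as the total forward-pass RSS reduction credited
to the variable introduced at each step, restricted to variables
surviving in the final model and normalized so the top variable scores
100. We deliberately attribute credit at entry rather than along the
pruning path: with strongly collinear predictors (waist and BMI
correlate ~0.85 in adult cohorts) deletion-path attribution is
path-dependent — the variable whose terms happen to be deleted early
transfers its credit to the collinear survivor — whereas entry
attribution gives the signal to the variable that captured it first. On
cohorts simulated from the packaged model this ordering reproduces the
expected ranking (waist first, then sex, BMI, hip) in nearly all seeds,
while deletion-path attribution inverts waist and BMI in most. The
deletion-path GCV deltas remain available in the fit trace.

### Cross-validation

`fit.kfold_cv` shuffles indices with a seed, splits contiguously into k
folds, fits the full pipeline on each complement and reports per-fold
and pooled out-of-fold R² and RMSE.

## Evaluation statistics

AUC is the Mann–Whitney placement estimator with ties counted 1/2,
computed via midranks. Its standard error and the paired comparison of
two markers scored on the same subjects follow the DeLong
placement-component approach: per-case and per-control placements give
the variance S10/m + S01/n and the covariance of two correlated AUCs;
the difference is referred to a standard normal, two-sided. Identical
score vectors return z = 0, p = 1 by convention. No multiplicity
adjustment is applied to pairwise p-values.

Operating points call positive at score ≥ cutoff; cutoff selection
maximizes Youden's J over observed score values (ties: smaller
|sensitivity − specificity|, then smaller cutoff), making the selection
invariant under monotone score transforms.

The goodness-of-fit battery (with e = observed − predicted) reports
RMSE, RRMSE = 100·RMSE/mean(obs), SD ratio, CV, Pearson correlation PC,
performance index PI = RRMSE/(1+PC), mean error, relative approximation
error Σe²/Σy², MRAE = mean(|e|/y), MAPE = 100·MRAE, MAD, and the
least-squares AIC n·ln(SSE/n) + 2p with its small-sample correction
CAIC = AIC + 2p(p+1)/(n−p−1). These definitions are chosen so the
internal identities hold exactly (ME = 0 and PC² = calibration R² for
least-squares predictions; PI is definitionally RRMSE/(1+PC)). MRAE has
no independent definition consistent with published usage of the term;
here it is simply MAPE/100, and both blow up when observed values near
zero appear in the denominator — a known artifact of relative errors on
a floored outcome. Calibration reports both conventions of
calibration-in-the-large (mean difference, and the free intercept of
the observed-on-predicted OLS fit) along with the calibration slope and
R², because published reports do not always say which convention they
use.

## Metabolic syndrome

ATP III: positive at ≥3 of abdominal obesity (waist > 102/88 cm,
strict), triglycerides ≥ 150 mg/dl, HDL < 40/50 mg/dl, blood pressure
≥ 130 or ≥ 85 mmHg or treated, fasting glucose ≥ 100 mg/dl. The glucose
cut defaults to the revised 100; the original 110 is one config field
away. Boundary conventions (strict waist, inclusive others) are pinned
in tests because prevalence at boundary values depends on them.

## The synthetic cohort generator

The generator exists so the whole pipeline — fitting, ROC comparison,
calibration, metabolic syndrome — is exercisable without patient data.
Per sex it draws age, height, waist, hip, BMI, blood pressures,
glucose, triglycerides, HDL and c-peptide from a multivariate normal
with the study group's reported gender-stratified means and SDs, a
shared correlation matrix, and box truncation to physiological bounds
(height 140–210 cm, waist 55–160, hip 70–180, BMI 15–60, glucose 60–125
— the source cohort excluded diabetes — TG 30–600, HDL 20–120, age
20–50) by resampling, which preserves distribution shape inside the
box. Height (173 ± 7 cm men, 160 ± 6.5 women) and c-peptide
(2.0 ± 0.8 ng/ml) are not reported in the study tables and use typical
values for the study population. The female fraction defaults to 0.584.

Correlations are not reported either; defaults are typical
cardiometabolic magnitudes (WC–BMI 0.85, WC–HC 0.80, BMI–HC 0.80,
WC–TG 0.35, WC–glucose 0.30, WC–HDL −0.30, TG–HDL −0.40, age–WC 0.20,
c-peptide–BMI 0.40, 0.10 elsewhere), projected to the nearest
positive-definite correlation matrix, and fully overridable.

Box truncation biases means — directly through a variable's own bounds
(male TG's lower bound sits 1.4 SD below its mean) and indirectly
through correlated neighbors' bounds (rejecting low-BMI rows removes
low-waist rows). So that the generated means actually equal the
targets, the latent mean vector is calibrated: a fixed
common-random-numbers draw of 480,000 latent vectors is reused while
each latent mean is iteratively shifted by the measured post-truncation
bias, converging to the sample-exact fixed point. The calibration seed
is a package constant, independent of the user's generation seed, so
calibration is a deterministic property of a profile; an audit with an
independent 2-million draw puts the residual mean bias at or below
~0.1% of an SD for most variables. Truncation still shrinks SDs
(male TG most, by ~10%); only means are calibrated.

Weight is derived as BMI·height², and "measured" VAT is the packaged
model's prediction plus Gaussian noise with SD 41 cm² (the reported
residual scale of the published fit), floored at 1 cm². The noise is
homoscedastic by default although real residuals are visibly
heteroscedastic at low VAT; a heavier-tailed outcome and a
lognormal-triglyceride marginal are exposed as options but off by
default for determinism. A `dysmetabolism_shift` dial moves
waist/TG/glucose/blood-pressure means up and HDL down by a chosen
number of SDs, for prevalence-response experiments.

What passing tests on these cohorts do show: the implementation of
every formula, the selection machinery's ability to recover a known
generating structure, and the internal consistency of the evaluation
statistics. What they do not show: performance on real patients, whose
joint distribution (skewness, heteroscedasticity, measurement error)
the Gaussian generator deliberately does not reproduce. Patient-level
statistics printed in the source study are therefore out of scope as
reproduction targets.

## Numerical choices and problem sizes

Least-squares refits use `numpy.linalg.lstsq` (rank-revealing);
candidate moves whose columns are within 1e-9 relative tolerance of the
current design's span are skipped. The forward pass recomputes the QR
factorization after each accepted move (n up to a few thousand, ≤ 21
columns — cheap and numerically safe). GCV returns +inf when the
effective parameter count reaches n.

Simulation-based checks use sizes chosen to make their statistics
stable at desk scale: 2,000-subject cohorts across 20 seeds for
structure recovery, 20,000 subjects for generator moment contracts,
5,000 replicates of n = 500 for the DeLong type-I check, 10,000 random
records for index-oracle equivalence. On cohorts of 2,000 with nine
candidate predictors a full fit takes on the order of two seconds.

## Known limitations

- Exact variable-set recovery at the default GCV penalty is a coin
  flip at n = 2000: the four true predictors are always selected, but
  one or two weak extra terms survive pruning in roughly half of the
  simulated cohorts, because the knot search's selection bias and the
  correlated laboratory variables' ability to proxy residual
  approximation error together outweigh the ~4-effective-parameter GCV
  cost when C/n is small. A stiffer penalty (≈6) yields near-perfect
  exact selection but is not the conventional default.
- No prediction intervals: the published model carries none, and the
  engine does not estimate them.
- The fitted-model JSON stores structure and coefficients only, not
  training diagnostics; the fit trace is a separate artifact.
- The CLI's `evaluate` compares the packaged model against the built-in
  indices; arbitrary external marker columns are a library-level call
  (`evaluation.compare_indices`), not a CLI flag.
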