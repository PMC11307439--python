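# vatpredict

Anthropometric prediction of visceral adipose tissue, for clinical
researchers who need a CT-free estimate of visceral adiposity and for
methodologists who want the full derivation and validation machinery
behind such models.

Visceral adipose tissue (VAT) — the fat depot most strongly linked to
cardiometabolic risk — is measured as a cross-sectional area (cm²) on a
CT slice at the L3 vertebral level. CT is accurate but expensive, so a
practical alternative is to predict the CT value from bedside
measurements. This package implements a published sex-specific model of
that kind, built with multivariate adaptive regression splines (MARS) on
a non-diabetic adult cohort, together with everything needed to derive,
compare and validate such models on tabular cohort data.

## The model

The predictor is a MARS model: a constant plus basis functions, each a
coefficient times a product of at most two hinge terms
max(0, ±(x − t)) or category indicators. The published final model uses
waist circumference (WC, cm), hip circumference (HC, cm), BMI (kg/m²)
and sex:

```
VAT = 249
      − 79.9·[female]
      − 4.4 ·max(0, 111 − WC)
      − 5.14·max(0, HC − 106)
      − 29.5·max(0, 25.9 − BMI)
      + 13  ·max(0, BMI − 25.9)
      + 7.18·[female]·max(0, 29 − BMI)
      + 0.459·max(0, 111 − WC)·max(0, 28.4 − BMI)
```

For a man at WC 111, HC 106 and BMI 25.9 every basis function vanishes
and the prediction is the constant, 249 cm². The model is continuous
and piecewise linear in each predictor.

## What's in the box

| module | contents |
| --- | --- |
| `vatpredict.cohort` | subject data model, validation, CSV round-tripping, unit conversions (canonical units: cm, kg, mmHg, mg/dl) |
| `vatpredict.model` | MARS model representation, the packaged published model, prediction, JSON serialization |
| `vatpredict.fit` | MARS engine: forward hinge selection with first-order interactions, GCV backward pruning, variable importance, k-fold CV |
| `vatpredict.indices` | comparator adiposity indices: VAI, LAP, ABSI, BRI, METS-IR, METS-VF, WHR, WHtR, BMI |
| `vatpredict.evaluation` | ROC with DeLong variance, paired DeLong AUC tests, Youden cutoff selection, goodness-of-fit battery, calibration (CITL/slope/R²) |
| `vatpredict.mets` | NCEP ATP III metabolic syndrome classifier |
| `vatpredict.simulate` | seeded synthetic cohorts with the study group's gender-stratified anthropometric/laboratory structure |
| `vatpredict.cli` | `vatpredict` command with predict / indices / mets / fit / evaluate / simulate subcommands |

## Worked example

Simulate a 400-subject cohort with the study group's distributional
structure, score it with the published model, and compare the model
against the comparator indices for detecting increased VAT (>130 cm²):

```sh
vatpredict simulate --n 400 --seed 11 --out demo.csv
vatpredict predict  --in demo.csv --out demo_pred.csv
vatpredict evaluate --in demo.csv --out demo_auc.csv --gof-out demo_gof.json
```

`demo_pred.csv` starts

```
subject_id,predicted_vat
S000000,72.9097421675722
S000001,182.04970551462313
S000002,84.00481138712635
```

— per-subject predicted VAT areas in cm². The first rows of
`demo_auc.csv` (values rounded here) are

```
stratum  marker     auc    se     p_vs_reference
male     new_model  0.955  0.019
male     VAI        0.525  0.053  5.9e-16
male     LAP        0.765  0.041  4.9e-07
male     ABSI       0.422  0.052  2.9e-23
male     BRI        0.857  0.033  1.1e-04
...
```

Each row is one marker's ability to detect increased VAT in one sex
stratum: the AUC with its DeLong standard error, and the DeLong paired
test p-value against the reference model. Because this cohort's
"measured" VAT was generated by the published model plus noise, the
model's AUC (0.955 in men here) sits at the top, with the purely
waist/BMI-driven indices behind it and lipid-only indices (VAI) near
chance — the qualitative pattern such comparisons show on real cohorts.
`demo_gof.json` reports the goodness-of-fit battery of the model
against the measured values (here RMSE 36.9 cm², Pearson r 0.896) and
the calibration fit (slope 0.994, R² 0.80): close to ideal, as expected
when the scoring model is the generating model.

Fitting your own model from a cohort CSV:

```sh
vatpredict fit --in cohort.csv --response ct_vat --out-model model.json \
               --out-importance importance.csv
```

Every subcommand writes a `<out>.manifest.json` (tool version, effective
configuration, seed, input checksum) sufficient to reproduce the run.

## Scope notes

The package does not handle CT images or adipose segmentation — it
starts from tabular measurements. The study's patient-level data are
not public, so patient-level statistics printed in the source study are
not reproduction targets; the synthetic generator emulates the reported
gender-stratified moments instead. See `docs/methods.md` for the model,
algorithmic and statistical details.
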