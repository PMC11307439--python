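import numpy as np
import pytest

from vatpredict.cohort import Cohort
from vatpredict.errors import DegenerateInputError, DomainError
from vatpredict.evaluation import (CalibrationReport, DelongComparison,
                                   GofReport, IncreasedVatRule, calibration,
                                   compare_indices, delong_paired_test, gof,
                                   operating_point, roc, select_cutoff)
from vatpredict.model import predict_vat_batch, published_vat_model
from vatpredict.simulate import GeneratorSpec, SyntheticProfile, generate

from .conftest import make_record


def brute_force_auc(scores, labels):
    """Concordant-pair fraction with ties counted 1/2 — O(mn) oracle."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def brute_force_delong(a, b, labels):
    """Independent placement-component calculation with explicit loops."""
    m = int(labels.sum())
    n = len(labels) - m
    out = []
    for scores in (a, b):
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        v10 = np.array([np.mean([1.0 if c > d else 0.5 if c == d else 0.0
                                 for d in controls]) for c in cases])
        v01 = np.array([np.mean([1.0 if c > d else 0.5 if c == d else 0.0
                                 for c in cases]) for d in controls])
        out.append((v10.mean(), v10, v01))
    auc_a, v10a, v01a = out[0]
    auc_b, v10b, v01b = out[1]
    var = (np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
           + np.var(v10b, ddof=1) / m + np.var(v01b, ddof=1) / n)
    cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
           + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
    z = (auc_a - auc_b) / np.sqrt(var - 2 * cov)
    return auc_a, auc_b, z


class TestRoc:
    def test_small_example(self):
        r = roc(np.array([3., 5., 1., 2., 4.]), np.array([1, 1, 0, 0, 0]))
        assert r.auc == pytest.approx(5 / 6)
        assert r.n_cases == 2 and r.n_controls == 3

    def test_perfect_separation(self):
        r = roc(np.array([10., 11., 1., 2.]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0 and r.se == 0.0

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 8, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_null_auc_near_half(self, rng):
        scores = rng.standard_normal(2000)
        labels = rng.integers(0, 2, 2000)
        r = roc(scores, labels)
        assert abs(r.auc - 0.5) <= 3 * r.se

    def test_curve_endpoints_monotone(self, rng):
        scores = rng.standard_normal(300)
        labels = rng.integers(0, 2, 300)
        curve = roc(scores, labels).curve
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        a = roc(scores, labels)
        b = roc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert np.allclose(a.curve, b.curve)

    def test_single_class_error(self):
        with pytest.raises(DegenerateInputError):
            roc(np.array([1., 2.]), np.array([1, 1]))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(10, 300))
            scores = rng.standard_normal(n).round(1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestDelong:
    def test_identical_scores(self, rng):
        s = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        cmp = delong_paired_test(s, s.copy(), labels)
        assert cmp.z == 0.0 and cmp.p == 1.0

    def test_hand_sized_example_matches_brute_force(self):
        a = np.array([0.9, 0.8, 0.35, 0.7, 0.2, 0.1])
        b = np.array([0.6, 0.9, 0.4, 0.2, 0.5, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        auc_a, auc_b, z = brute_force_delong(a, b, labels)
        cmp = delong_paired_test(a, b, labels)
        assert cmp.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert cmp.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert cmp.z == pytest.approx(z, abs=1e-10)

    def test_random_examples_match_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            a = rng.standard_normal(n)
            b = 0.5 * a + rng.standard_normal(n)
            want = brute_force_delong(a, b, labels)
            got = delong_paired_test(a, b, labels)
            if np.isfinite(want[2]):
                assert got.z == pytest.approx(want[2], abs=1e-9)

    def test_variance_close_to_bootstrap(self, rng):
        n = 300
        labels = np.r_[np.ones(n // 3, int), np.zeros(n - n // 3, int)]
        scores = labels * 1.0 + rng.standard_normal(n)
        r = roc(scores, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            boots.append(roc(scores[idx], labels[idx]).auc)
        assert r.var == pytest.approx(np.var(boots, ddof=1), rel=0.10)


class TestOperatingPoints:
    def test_example_counts(self):
        scores = np.array([3., 5., 1., 2., 4.])
        labels = np.array([1, 1, 0, 0, 0])
        sens, spec = operating_point(scores, labels, 3.0)
        assert sens == 1.0 and spec == pytest.approx(2 / 3)

    def test_extreme_cutoffs(self):
        scores = np.array([3., 5., 1., 2., 4.])
        labels = np.array([1, 1, 0, 0, 0])
        assert operating_point(scores, labels, -10.0) == (1.0, 0.0)
        assert operating_point(scores, labels, 10.0) == (0.0, 1.0)

    def test_select_cutoff_separable(self):
        scores = np.array([1., 2., 3., 4.])
        labels = np.array([0, 0, 1, 1])
        cutoff, sens, spec = select_cutoff(scores, labels)
        assert cutoff == 3.0 and sens == 1.0 and spec == 1.0

    def test_select_cutoff_all_tied_scores(self):
        cutoff, sens, spec = select_cutoff(np.array([2., 2., 2., 2.]),
                                           np.array([0, 1, 0, 1]))
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_select_cutoff_rank_invariance(self, rng):
        scores = rng.standard_normal(100)
        labels = (scores + rng.standard_normal(100) > 0).astype(int)
        c1, s1, p1 = select_cutoff(scores, labels)
        c2, s2, p2 = select_cutoff(np.exp(scores), labels)
        assert c2 == pytest.approx(np.exp(c1))
        assert (s1, p1) == (s2, p2)


class TestCompareIndices:
    def _cohort_with_outcome_from_model(self, seed, n=250):
        cohort = generate(GeneratorSpec(profile=SyntheticProfile(), n=n,
                                        seed=seed))
        return cohort

    def test_model_score_wins_when_it_generated_outcome(self):
        model = published_vat_model()
        wins = 0
        trials = 30
        for seed in range(trials):
            cohort = self._cohort_with_outcome_from_model(seed)
            preds, _ = predict_vat_batch(model, cohort)
            markers = {
                "new_model": preds.to_numpy(),
                "wc": np.array([r.wc for r in cohort]),
                "whr": np.array([r.wc / r.hc for r in cohort]),
            }
            table = compare_indices(cohort, IncreasedVatRule(130.0), markers,
                                    "new_model", stratify_by_sex=False)
            table = table[table.marker.notna()]
            best = table.sort_values("auc").iloc[-1]["marker"]
            wins += best == "new_model"
        assert wins >= 0.9 * trials

    def test_reference_vs_itself_p_is_nan_and_duplicate_is_one(self):
        cohort = self._cohort_with_outcome_from_model(1)
        model = published_vat_model()
        preds, _ = predict_vat_batch(model, cohort)
        markers = {"new_model": preds.to_numpy(),
                   "copy": preds.to_numpy().copy()}
        table = compare_indices(cohort, IncreasedVatRule(130.0), markers,
                                "new_model", stratify_by_sex=False)
        ref_row = table[table.marker == "new_model"].iloc[0]
        copy_row = table[table.marker == "copy"].iloc[0]
        assert np.isnan(ref_row["p_vs_reference"])
        assert copy_row["p_vs_reference"] == 1.0

    def test_permuted_outcome_gives_null_aucs(self, rng):
        cohort = self._cohort_with_outcome_from_model(2, n=600)
        # shuffle measured VAT across subjects: markers become noise
        vat = np.array([r.ct_vat for r in cohort])
        rng.shuffle(vat)
        shuffled = Cohort(records=[r.replace(ct_vat=float(v))
                                   for r, v in zip(cohort, vat)])
        preds, _ = predict_vat_batch(published_vat_model(), shuffled)
        markers = {"new_model": preds.to_numpy()}
        table = compare_indices(shuffled, IncreasedVatRule(130.0), markers,
                                "new_model", stratify_by_sex=False)
        row = table.iloc[0]
        assert abs(row["auc"] - 0.5) <= 3 * row["se"]

    def test_single_class_stratum_skipped(self):
        records = [make_record(subject_id=f"m{i}", ct_vat=200.0 + i)
                   for i in range(5)]
        records += [make_record(subject_id=f"f{i}", sex="female",
                                ct_vat=100.0 + i) for i in range(5)]
        cohort = Cohort(records=records)
        markers = {"wc": np.array([r.wc for r in cohort])}
        table = compare_indices(cohort, IncreasedVatRule(130.0), markers, "wc")
        male_rows = table[table.stratum == "male"]
        assert "skipped" in male_rows.iloc[0]["note"]


class TestGof:
    def test_perfect_predictions(self, rng):
        obs = rng.uniform(50, 300, 40)
        rep = gof(obs, obs.copy(), n_params=3)
        assert rep.rmse == 0 and rep.me == 0 and rep.rae == 0
        assert rep.mape == 0 and rep.mad == 0 and rep.sdr == 0
        assert rep.pc == pytest.approx(1.0)

    def test_hand_example(self):
        rep = gof(np.array([10., 20., 30.]), np.array([12., 18., 30.]),
                  n_params=1)
        assert rep.rmse == pytest.approx(1.6329931618554518)
        assert rep.mad == pytest.approx(4 / 3)
        assert rep.mape == pytest.approx(10.0)
        assert rep.rae == pytest.approx(8 / 1400)
        assert rep.mrae == pytest.approx(0.1)

    def test_least_squares_identities(self, rng):
        # me = 0 and pc² = calibration R² when predictions come from OLS
        x = rng.uniform(0, 10, 200)
        y = 3 * x + rng.normal(0, 2, 200)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        rep = gof(y, pred, n_params=2)
        cal = calibration(y, pred)
        assert rep.me == pytest.approx(0.0, abs=1e-9)
        assert rep.pc ** 2 == pytest.approx(cal.rsq, abs=1e-12)
        assert rep.pi == pytest.approx(rep.rrmse / (1 + rep.pc), rel=1e-12)

    def test_published_pi_relation_scale(self):
        # the performance-index identity at the published values:
        # RRMSE 31 and PC 0.884 give PI = 31/1.884
        assert 31 / (1 + 0.884) == pytest.approx(16.45, abs=0.01)

    def test_rmse_at_least_mad(self, rng):
        obs = rng.uniform(10, 100, 50)
        pred = obs + rng.normal(0, 5, 50)
        rep = gof(obs, pred)
        assert rep.rmse >= rep.mad >= 0

    def test_aic_caic_relation(self, rng):
        obs = rng.uniform(10, 100, 60)
        pred = obs + rng.normal(0, 5, 60)
        p = 8
        rep = gof(obs, pred, n_params=p)
        assert rep.caic == pytest.approx(rep.aic + 2 * p * (p + 1) / (60 - p - 1))


class TestCalibration:
    def test_perfect(self, rng):
        pred = rng.uniform(0, 100, 30)
        rep = calibration(pred.copy(), pred)
        assert rep.slope == pytest.approx(1.0)
        assert rep.citl_mean_diff == pytest.approx(0.0, abs=1e-9)
        assert rep.rsq == pytest.approx(1.0)

    def test_affine_offset(self, rng):
        pred = rng.uniform(0, 100, 30)
        rep = calibration(pred + 10.0, pred)
        assert rep.slope == pytest.approx(1.0)
        assert rep.citl_intercept == pytest.approx(10.0)
        assert rep.citl_mean_diff == pytest.approx(10.0)

    def test_slope_recovery_in_noiseless_limit(self, rng):
        pred = rng.uniform(0, 100, 200)
        obs = 5.0 + 0.8 * pred
        assert calibration(obs, pred).slope == pytest.approx(0.8, abs=1e-10)

    def test_overdispersed_predictions_recover_inverse_factor(self, rng):
        truth = rng.uniform(0, 100, 200)
        k = 2.5
        pred = truth.mean() + k * (truth - truth.mean())
        assert calibration(truth, pred).slope == pytest.approx(1 / k, abs=1e-10)

    def test_constant_predictions_error(self):
        with pytest.raises(DomainError):
            calibration(np.array([1., 2., 3.]), np.array([5., 5., 5.]))
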