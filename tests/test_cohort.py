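"""Phenotype derivation, weighted-cohort correction, censored regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from carriermr.cohort import (
    CohortError,
    IncidenceTable,
    RecordExcluded,
    compute_cohort_weights,
    derive_cohort_phenotypes,
    derive_menopause_phenotype,
    fit_censored_regression,
    validate_instruments,
)
from carriermr.scores import compute_scores
from carriermr.synthetic import CohortScenario, cohort_dosage_matrix, gen_carrier_cohort


def rec(**kw):
    base = {
        "period_past_year": None, "periods_stopped": None, "reason": None,
        "age_last_menstruation": None, "age_menopause": None, "age_rrso": None,
        "age_cancer_diagnosis": None, "age_death": None, "age_interview": None,
    }
    base.update(kw)
    return base


class TestPhenotypeDerivation:
    """Exhaustive worked table of questionnaire-record rules."""

    def test_natural_menopause_preceding_rrso(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause", age_menopause=49, age_rrso=52,
                age_interview=55, periods_stopped=True)
        )
        assert obs.event and obs.value == 49

    def test_plus_one_year_rule(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause", period_past_year=False,
                age_last_menstruation=50, age_interview=58, periods_stopped=True)
        )
        assert obs.event and obs.value == 51

    def test_admin_cap_for_late_premenopausal(self):
        obs = derive_menopause_phenotype(
            rec(period_past_year=True, periods_stopped=False, age_interview=63)
        )
        assert obs.event and obs.value == 60 and obs.reason == "admin_cap"

    def test_menopause_after_rrso_censored_at_rrso(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause", age_menopause=53, age_rrso=52,
                age_interview=55, periods_stopped=True)
        )
        assert not obs.event and obs.value == 52

    def test_menopause_after_diagnosis_censored(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause", age_menopause=50,
                age_cancer_diagnosis=45, age_interview=55, periods_stopped=True)
        )
        assert not obs.event and obs.value == 45

    def test_surgical_reason_censored_at_last_period(self):
        obs = derive_menopause_phenotype(
            rec(reason="rrso", age_last_menstruation=44, age_rrso=44,
                age_interview=50, periods_stopped=True)
        )
        assert not obs.event and obs.value == 44

    def test_hysterectomy_censored(self):
        obs = derive_menopause_phenotype(
            rec(reason="hysterectomy", age_last_menstruation=47, age_interview=52,
                periods_stopped=True)
        )
        assert not obs.event and obs.value == 47

    def test_medication_under_40_premenopausal(self):
        obs = derive_menopause_phenotype(
            rec(reason="medication", age_last_menstruation=35, age_interview=38,
                periods_stopped=True)
        )
        assert not obs.event and obs.value == 38  # censored at interview

    def test_medication_40plus_censored_at_last_period(self):
        obs = derive_menopause_phenotype(
            rec(reason="medication", age_last_menstruation=45, age_interview=50,
                periods_stopped=True)
        )
        assert not obs.event and obs.value == 45

    def test_medication_missing_interview_age_excluded(self):
        with pytest.raises(RecordExcluded, match="interview"):
            derive_menopause_phenotype(
                rec(reason="medication", age_last_menstruation=35, periods_stopped=True)
            )

    def test_pregnancy_premenopausal(self):
        obs = derive_menopause_phenotype(
            rec(reason="pregnancy", periods_stopped=True, age_interview=33)
        )
        assert not obs.event and obs.value == 33

    def test_mixed_reason_not_natural_event(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause+chemotherapy", age_last_menstruation=48,
                age_interview=55, periods_stopped=True)
        )
        assert not obs.event  # natural menopause must be the sole reason

    def test_stopped_missing_ages_excluded(self):
        with pytest.raises(RecordExcluded, match="missing"):
            derive_menopause_phenotype(
                rec(reason="natural_menopause", periods_stopped=True, age_interview=50)
            )

    def test_menopause_after_interview_excluded(self):
        with pytest.raises(RecordExcluded, match="after_interview"):
            derive_menopause_phenotype(
                rec(reason="natural_menopause", age_menopause=56, age_interview=53,
                    periods_stopped=True)
            )

    def test_negative_age_excluded(self):
        with pytest.raises(RecordExcluded, match="negative"):
            derive_menopause_phenotype(
                rec(period_past_year=True, age_interview=-3)
            )

    def test_natural_event_at_cap_becomes_admin(self):
        obs = derive_menopause_phenotype(
            rec(reason="natural_menopause", age_menopause=61, age_interview=65,
                periods_stopped=True), admin_cap=60
        )
        assert obs.event and obs.value == 60 and obs.reason == "admin_cap"

    def test_premenopausal_censored_at_earliest_event(self):
        obs = derive_menopause_phenotype(
            rec(period_past_year=True, age_interview=50, age_cancer_diagnosis=46)
        )
        assert not obs.event and obs.value == 46

    def test_cohort_vector_version_logs_exclusions(self):
        cohort = pd.DataFrame([
            rec(reason="natural_menopause", age_menopause=49, age_interview=55,
                periods_stopped=True),
            rec(reason="natural_menopause", periods_stopped=True, age_interview=50),
        ])
        cohort["id"] = ["a", "b"]
        obs, excl = derive_cohort_phenotypes(cohort)
        assert len(obs) == 1 and len(excl) == 1
        assert excl["reason"].iloc[0] == "missing_age_at_menopause"


class TestCohortWeights:
    def incidence(self):
        return IncidenceTable((18, 40), (40, 60), (0.005, 0.01))

    def test_matching_fractions_give_unit_weights(self):
        inc = self.incidence()
        ages = np.array([30.0] * 100)
        p = float(np.atleast_1d(inc.prob_affected_by(29.0))[0])  # midpoint of (18, 40)
        n_aff = int(round(p * 100))
        affected = np.array([True] * n_aff + [False] * (100 - n_aff))
        cw = compute_cohort_weights(ages, affected, inc, (18, 40))
        np.testing.assert_allclose(cw.weights, p * 100 / n_aff * affected
                                   + (1 - p) * 100 / (100 - n_aff) * ~affected)

    def test_closed_form_weights(self):
        # N=100, 50 affected, implied p=0.2 -> w_aff=0.4, w_unaff=1.6
        rate = -np.log(1 - 0.2) / 11.0  # cumulative hazard to midpoint 29 gives p=0.2
        inc = IncidenceTable((18,), (40,), (rate,))
        ages = np.full(100, 30.0)
        affected = np.array([True] * 50 + [False] * 50)
        cw = compute_cohort_weights(ages, affected, inc, (18, 40))
        np.testing.assert_allclose(cw.weights[affected], 0.4, rtol=1e-12)
        np.testing.assert_allclose(cw.weights[~affected], 1.6, rtol=1e-12)

    def test_weighted_fraction_identity(self, rng):
        inc = self.incidence()
        ages = rng.uniform(20, 59, 500)
        affected = rng.random(500) < 0.4  # heavily oversampled
        cw = compute_cohort_weights(ages, affected, inc, (18, 30, 40, 50, 60))
        for _, row in cw.diagnostics.iterrows():
            assert row["weighted_fraction"] == pytest.approx(row["p_implied"], abs=1e-12)

    def test_reweighting_recovers_population_incidence(self, score_model):
        # oversampled cohort reweighted -> weighted affected fraction close to
        # the population fraction from a non-oversampled cohort
        sc_pop = CohortScenario(n_families=1500, oversample_affected=1.0, seed=5)
        sc_over = CohortScenario(n_families=1500, oversample_affected=3.0, seed=5)
        pop = gen_carrier_cohort(sc_pop, score_model)
        over = gen_carrier_cohort(sc_over, score_model)
        assert over["affected"].mean() > pop["affected"].mean() + 0.05
        ages = over["age_interview"].fillna(over["age_death"])
        cw = compute_cohort_weights(ages, over["affected"], sc_over.incidence(),
                                    (18, 30, 40, 50, 60, 80))
        weighted_frac = np.average(over["affected"], weights=cw.weights)
        assert weighted_frac == pytest.approx(pop["affected"].mean(), abs=0.03)

    def test_positive_rates_required(self):
        with pytest.raises(CohortError):
            IncidenceTable((18, 40), (40, 60), (-0.01, 0.01))

    def test_contiguity_required(self):
        with pytest.raises(CohortError):
            IncidenceTable((18, 45), (40, 60), (0.01, 0.01))


class TestCensoredRegression:
    def make_data(self, rng, n=400, beta=(2.0, 1.5), censor_at=None):
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.standard_normal(n)})
        y = X.to_numpy() @ np.asarray(beta) + rng.normal(0, 1.0, n) + 50
        beta = np.asarray(beta) + np.array([50.0, 0])
        if censor_at is None:
            return y, np.ones(n, dtype=bool), X
        event = y < censor_at
        return np.minimum(y, censor_at), event, X

    def test_no_censoring_equals_ols(self, rng):
        y, event, X = self.make_data(rng)
        fit = fit_censored_regression(y, event, X)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef, ols.params, atol=1e-6)

    def test_parameter_recovery_under_censoring(self, rng):
        y, event, X = self.make_data(rng, n=2000, censor_at=52.5)
        assert 0.2 < event.mean() < 0.8
        fit = fit_censored_regression(y, event, X)
        assert abs(fit.coefficient("x") - 1.5) < 2 * fit.coefficient_se("x")

    def test_cluster_duplication_sandwich_algebra(self, rng):
        # duplicating every cluster leaves the coefficient unchanged and
        # shrinks the cluster-robust SE by sqrt(2) (after removing the
        # G/(G-1) small-sample factor, which differs between the two fits)
        y, event, X = self.make_data(rng, n=300, censor_at=52.5)
        clusters = np.arange(300)
        fit1 = fit_censored_regression(y, event, X, clusters=clusters)
        y2 = np.concatenate([y, y])
        e2 = np.concatenate([event, event])
        X2 = pd.concat([X, X], ignore_index=True)
        cl2 = np.concatenate([clusters, clusters + 300])
        fit2 = fit_censored_regression(y2, e2, X2, clusters=cl2)
        np.testing.assert_allclose(fit2.coef, fit1.coef, atol=1e-5)
        g1, g2 = fit1.n_clusters, fit2.n_clusters
        corr = np.sqrt((g1 / (g1 - 1)) / (g2 / (g2 - 1)))
        ratio = fit1.coefficient_se("x") / fit2.coefficient_se("x") * corr
        assert ratio == pytest.approx(np.sqrt(2), rel=0.02)

    def test_weight_scale_invariance(self, rng):
        y, event, X = self.make_data(rng, n=300, censor_at=52.5)
        w = rng.uniform(0.5, 2.0, 300)
        fit1 = fit_censored_regression(y, event, X, weights=w)
        fit2 = fit_censored_regression(y, event, X, weights=7.3 * w)
        np.testing.assert_allclose(fit2.coef, fit1.coef, atol=1e-6)
        np.testing.assert_allclose(fit2.se, fit1.se, rtol=1e-4)

    def test_nll_monotone_over_accepted_iterations(self, rng):
        y, event, X = self.make_data(rng, n=500, censor_at=52.0)
        fit = fit_censored_regression(y, event, X)
        path = np.asarray(fit.nll_path)
        assert np.all(np.diff(path) <= 1e-8 * np.abs(path[:-1]))

    def test_all_censored_errors(self, rng):
        y, _, X = self.make_data(rng, n=50)
        with pytest.raises(CohortError):
            fit_censored_regression(y, np.zeros(50, dtype=bool), X)

    def test_rank_deficiency_errors(self, rng):
        y, event, X = self.make_data(rng, n=50)
        X = X.copy()
        X["x2"] = X["x"]
        with pytest.raises(CohortError, match="rank"):
            fit_censored_regression(y, event, X)

    def test_coverage_of_cluster_robust_ci(self, score_model):
        # nominal 95% CIs across simulated cohorts cover the truth
        hits = 0
        n_rep = 120
        for s in range(n_rep):
            sc = CohortScenario(n_families=250, members_per_family=(1, 2),
                                gs_true_effect=1.5, seed=s)
            cohort = gen_carrier_cohort(sc, score_model)
            scores = compute_scores(score_model, cohort_dosage_matrix(cohort))
            fit, _ = validate_instruments(cohort, scores["score_std"],
                                          sc.incidence(), trait="anm")
            b = fit.coefficient("score")
            se = fit.coefficient_se("score")
            hits += (b - 1.96 * se) <= 1.5 <= (b + 1.96 * se)
        # binomial(120, 0.95) 2-sigma ~ 0.04
        assert hits / n_rep == pytest.approx(0.95, abs=0.06)


class TestValidateInstruments:
    def test_end_to_end_recovery(self, score_model):
        sc = CohortScenario(n_families=1500, gs_true_effect=1.5, seed=11)
        cohort = gen_carrier_cohort(sc, score_model)
        scores = compute_scores(score_model, cohort_dosage_matrix(cohort))
        fit, excl = validate_instruments(cohort, scores["score_std"],
                                         sc.incidence(), trait="anm")
        assert abs(fit.coefficient("score") - 1.5) < 2 * fit.coefficient_se("score")
        assert fit.n_censored > 0

    def test_aam_reduces_to_linear_regression(self, score_model):
        sc = CohortScenario(n_families=400, gs_true_effect=0.4, trait="aam",
                            aam_sd=1.5, seed=21)
        cohort = gen_carrier_cohort(sc, score_model)
        scores = compute_scores(score_model, cohort_dosage_matrix(cohort))
        fit, _ = validate_instruments(cohort, scores["score_std"],
                                      sc.incidence(), trait="aam", use_weights=False)
        assert fit.n_censored == 0
        assert abs(fit.coefficient("score") - 0.4) < 2 * fit.coefficient_se("score")
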