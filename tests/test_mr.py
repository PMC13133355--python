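"""Univariable MR estimator suite against closed-form and WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from carriermr.mr import (
    MRError,
    MREstimate,
    compare_estimates,
    egger,
    heterogeneity,
    ivw,
    median_estimators,
    radial_outliers,
    ratio_estimates,
)
from carriermr.sumstats import harmonize
from carriermr.synthetic import SumstatsScenario, gen_twosample_sumstats

from conftest import make_iset, random_iset


class TestRatioEstimates:
    def test_closed_form(self):
        iset = make_iset([0.1], [0.01], [0.05], [0.02])
        ratios, ses, dropped = ratio_estimates(iset)
        assert ratios[0] == pytest.approx(0.5)
        assert ses[0] == pytest.approx(0.2)
        assert dropped == 0

    def test_sign_flip_invariance(self, rng):
        iset = random_iset(rng, n=10)
        r1, s1, _ = ratio_estimates(iset)
        flipped = iset.subset(np.ones(10, dtype=bool))
        flipped.data["beta_exposure"] *= -1
        flipped.data["beta_outcome"] *= -1
        r2, s2, _ = ratio_estimates(flipped)
        np.testing.assert_allclose(r2, r1)
        np.testing.assert_allclose(s2, s1)

    def test_delta_method_oracle(self, rng):
        # brute-force first-order delta SE on a 5-SNP toy set
        bx = rng.uniform(0.05, 0.2, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        by = rng.normal(0, 0.05, 5)
        iset = make_iset(bx, 0.01 * np.ones(5), by, sy)
        _, ses, _ = ratio_estimates(iset)
        for j in range(5):
            grad = 1.0 / bx[j]  # d(by/bx)/d(by)
            np.testing.assert_allclose(ses[j], abs(grad) * sy[j], atol=1e-12)

    def test_empty_set_errors(self):
        iset = make_iset([], [], [], [])
        with pytest.raises(MRError):
            ratio_estimates(iset)


class TestIVW:
    def test_two_snp_exact(self):
        iset = make_iset([1.0, 1.0], [0.1, 0.1], [0.5, 0.5], [1.0, 1.0])
        est, het = ivw(iset)
        assert est.estimate == pytest.approx(0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-12)

    def test_fixed_vs_random_agree_when_homogeneous(self, rng):
        iset = random_iset(rng, n=40, theta=0.02)
        fixed, het = ivw(iset, weight_mode="fixed")
        mre, _ = ivw(iset, weight_mode="multiplicative_random")
        assert fixed.estimate == pytest.approx(mre.estimate)
        if het.Q <= het.df:
            assert mre.se == pytest.approx(fixed.se)
        else:
            assert mre.se >= fixed.se

    @pytest.mark.parametrize("seed", range(5))
    def test_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        iset = random_iset(rng, n=50, theta=np.log(1.04))
        est, _ = ivw(iset, weight_mode="fixed")
        w = 1.0 / iset.se_outcome**2
        fit = sm.WLS(iset.beta_outcome, iset.beta_exposure[:, None], weights=w).fit()
        assert est.estimate == pytest.approx(fit.params[0], abs=1e-10)
        assert abs(est.estimate - np.log(1.04)) < 2 * est.se * 2  # loose recovery guard

    def test_penalized_downweights_outlier(self, rng):
        iset = random_iset(rng, n=30, theta=0.0)
        iset.data.loc[0, "beta_outcome"] += 0.5  # gross outlier
        plain, _ = ivw(iset)
        pen, _ = ivw(iset, penalized=True)
        assert abs(pen.estimate) < abs(plain.estimate)

    def test_robust_resists_outlier(self, rng):
        iset = random_iset(rng, n=30, theta=0.0)
        iset.data.loc[0, "beta_outcome"] += 0.5
        rob, _ = ivw(iset, robust=True)
        plain, _ = ivw(iset)
        assert abs(rob.estimate) < abs(plain.estimate)

    def test_exp_ci_brackets_hr(self, rng):
        est, _ = ivw(random_iset(rng, n=20, theta=0.05))
        lo, hi = est.hr_ci
        assert lo < est.hr < hi

    def test_too_few_snps(self):
        with pytest.raises(MRError):
            ivw(make_iset([0.1], [0.01], [0.01], [0.01]))


class TestEgger:
    def test_exact_algebra_no_noise(self):
        # alpha = 0.01 on every SNP, no sampling noise: intercept and slope exact
        bx = np.array([0.05, 0.08, 0.12, 0.2, 0.15])
        theta = 0.04
        by = theta * bx + 0.01
        iset = make_iset(bx, 0.001 * np.ones(5), by, 0.02 * np.ones(5))
        est = egger(iset)
        assert est.estimate == pytest.approx(theta, abs=1e-10)
        assert est.intercept == pytest.approx(0.01, abs=1e-10)

    def test_balanced_pleiotropy_type_i_error(self):
        # intercept test should reject ~5% under balanced pleiotropy
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            sc = SumstatsScenario(n_snps=50, theta=0.03, seed=s,
                                  pleiotropy_mode="balanced", pleiotropy_sd=0.02,
                                  prop_invalid=1.0, palindromic_fraction=0.0)
            ex, out, _, _ = gen_twosample_sumstats(sc)
            est = egger(harmonize(ex, out))
            rejections += est.intercept_p < 0.05
        # binomial(200, 0.05): 2 sigma ~ 0.031
        assert rejections / n_rep == pytest.approx(0.05, abs=0.05)

    def test_directional_pleiotropy_recovery(self):
        # InSIDE holds: Egger slope tracks truth where IVW is biased
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            sc = SumstatsScenario(n_snps=100, theta=0.04, seed=s,
                                  pleiotropy_mode="directional", pleiotropy_mean=0.01,
                                  pleiotropy_sd=0.004, prop_invalid=1.0)
            ex, out, _, _ = gen_twosample_sumstats(sc)
            est = egger(harmonize(ex, out))
            hits += abs(est.estimate - 0.04) <= 2 * est.se
        assert hits / n_rep >= 0.75

    def test_too_few_snps(self):
        with pytest.raises(MRError):
            egger(make_iset([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2))


class TestMedians:
    def test_simple_median_closed_form(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 3.0], [1.0] * 3)
        est = median_estimators(iset, "simple", n_boot=100, seed=0)
        assert est.estimate == pytest.approx(2.0)

    def test_dominant_weight_breakdown(self):
        # one SNP carrying >50% of weight pins the weighted median to its ratio
        iset = make_iset([1.0, 1.0, 1.0], [0.001] * 3, [1.0, 2.0, 3.0],
                         [0.01, 1.0, 1.0])
        est = median_estimators(iset, "weighted", n_boot=100, seed=0)
        # interpolation across the cumulative weight function leaves a
        # deviation of order (other weight)/(dominant weight)
        assert est.estimate == pytest.approx(1.0, abs=1e-3)

    def test_majority_validity(self):
        # 30% invalid with large pleiotropy in weak instruments: the weighted
        # median stays near the truth while IVW is dragged away
        ok_median = ok_ivw = 0
        n_rep = 30
        for s in range(n_rep):
            sc = SumstatsScenario(n_snps=60, theta=0.0, seed=s,
                                  pleiotropy_mode="directional", pleiotropy_mean=0.1,
                                  pleiotropy_sd=0.02, prop_invalid=0.3,
                                  invalid_weakest=True)
            ex, out, _, _ = gen_twosample_sumstats(sc)
            iset = harmonize(ex, out)
            med = median_estimators(iset, "weighted", n_boot=200, seed=s)
            fe, _ = ivw(iset, weight_mode="fixed")
            ok_median += abs(med.estimate) <= 2 * med.se
            ok_ivw += abs(fe.estimate) > 2 * fe.se
        assert ok_median / n_rep >= 0.8
        assert ok_ivw / n_rep >= 0.6

    def test_unknown_variant(self, rng):
        with pytest.raises(MRError):
            median_estimators(random_iset(rng), "mode", n_boot=100)


class TestRadialOutliers:
    def test_homogeneous_no_outliers(self, rng):
        iset = random_iset(rng, n=40, theta=0.02)
        outliers, trimmed = radial_outliers(iset, alpha_level=0.001)
        assert outliers == []
        assert trimmed.n_snps == 40

    def test_injected_outlier_flagged(self, rng):
        iset = random_iset(rng, n=40, theta=0.02)
        iset.data.loc[5, "beta_outcome"] += 10 * iset.data.loc[5, "se_outcome"]
        outliers, trimmed = radial_outliers(iset)
        assert "rs6" in outliers
        assert trimmed.n_snps < 40
        assert set(trimmed.exclusions["reason"]) == {"radial_outlier"}

    def test_q_decomposition_identity(self, rng):
        iset = random_iset(rng, n=25, theta=0.03)
        est, _ = ivw(iset, weight_mode="fixed")
        het = heterogeneity(iset, est.estimate)
        assert het.contributions.sum() == pytest.approx(het.Q, abs=1e-10)


class TestHeterogeneity:
    def test_proportional_set_q_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        iset = make_iset(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        het = heterogeneity(iset, 0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0

    def test_df_is_n_minus_one(self, rng):
        for n in (5, 17):
            het = heterogeneity(random_iset(rng, n=n), 0.0)
            assert het.df == n - 1

    def test_null_distribution(self):
        # homogeneous replicates: Q ~ chi2(n-1), ~5% rejections at alpha=0.05
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            iset = random_iset(rng, n=20, theta=0.02)
            est, het = ivw(iset, weight_mode="fixed")
            rejections += het.p_value < 0.05
        bound = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep == pytest.approx(0.05, abs=bound + 0.01)

    def test_i2_matches_definition(self, rng):
        iset = random_iset(rng, n=30)
        het = heterogeneity(iset, 0.0)
        assert het.i2 == pytest.approx(max(0.0, (het.Q - het.df) / het.Q))


class TestCompareEstimates:
    def a(self, est, se):
        return MREstimate.from_point("IVW", est, se, 10)

    def test_identical(self):
        z, p = compare_estimates(self.a(0.05, 0.01), self.a(0.05, 0.01))
        assert z == 0.0
        assert p == 1.0

    def test_closed_form(self):
        z, p = compare_estimates(self.a(0.04, 0.005), self.a(0.02, 0.008))
        assert z == pytest.approx(2.12, abs=0.005)
        assert p == pytest.approx(0.034, abs=0.001)

    def test_antisymmetry(self):
        z1, p1 = compare_estimates(self.a(0.04, 0.005), self.a(0.02, 0.008))
        z2, p2 = compare_estimates(self.a(0.02, 0.008), self.a(0.04, 0.005))
        assert z2 == -z1
        assert p2 == p1

    def test_scale_mismatch(self):
        b = self.a(0.02, 0.008)
        b.scale = "linear"
        with pytest.raises(MRError, match="scale"):
            compare_estimates(self.a(0.04, 0.005), b)


class TestOrderingInvariance:
    def test_estimators_invariant_to_snp_order(self, rng):
        iset = random_iset(rng, n=25, theta=0.04)
        perm = rng.permutation(25)
        shuffled = iset.subset(np.ones(25, dtype=bool))
        shuffled.data = shuffled.data.iloc[perm].reset_index(drop=True)
        for fn in (lambda s: ivw(s)[0].estimate,
                   lambda s: egger(s).estimate,
                   lambda s: median_estimators(s, "weighted", n_boot=100, seed=0).estimate):
            assert fn(shuffled) == pytest.approx(fn(iset), abs=1e-12)
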