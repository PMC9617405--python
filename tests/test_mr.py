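"""Liability-scale MR estimator tests: oracles, scaling identities, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from coarsemr.containers import ConfigError, DataError
from coarsemr.mr import (
    cochran_q,
    estimate_theta2_lower_bound,
    fit_genetic_share,
    instrument_strength_lrt,
    ivw_combine,
    liability_wald_ratios,
    outcome_scan,
    prs_method,
    score_associations,
    sensitivity_sweep,
)
from coarsemr.simulate import simple_mr_config, simulate_cohort
from tests.conftest import oracle_poisson_log, oracle_probit


def _ratio_table(rows):
    return pd.DataFrame(
        rows, columns=["snp", "beta_y", "se_y", "c", "gamma_star", "wald", "wald_se"]
    ).set_index("snp")


class TestGeneticShareFit:
    def test_matches_direct_probit_likelihood_maximisation(self, tiny_binary_fit_data):
        y, X = tiny_binary_fit_data
        Z = pd.DataFrame({"g": X[:, 1]})
        M = pd.DataFrame({"x": X[:, 2]})
        fit = fit_genetic_share(y, Z, M)
        oracle = oracle_probit(y, X)
        assert fit.coef["g"] == pytest.approx(oracle[1], abs=1e-6)
        assert fit.confounder_coef["x"] == pytest.approx(oracle[2], abs=1e-6)

    def test_zero_information_instruments(self, rng):
        D = rng.binomial(1, 0.3, 200).astype(float)
        Z = pd.DataFrame({"z1": np.zeros(200), "z2": np.zeros(200)})
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_genetic_share(D, Z, None)
        assert (fit.coef == 0).all()
        assert fit.llf == pytest.approx(fit.llnull)
        stat, df, p = instrument_strength_lrt(fit)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_constant_exposure_rejected(self):
        with pytest.raises(DataError, match="constant"):
            fit_genetic_share(np.ones(50), pd.DataFrame({"z": np.arange(50) % 3}), None)

    def test_collinear_instruments_rejected_with_names(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        D = rng.binomial(1, 0.3, 300).astype(float)
        Z = pd.DataFrame({"a": g, "b": g.copy()})
        with pytest.raises(DataError):
            fit_genetic_share(D, Z, None)

    def test_full_ll_at_least_null_ll(self, rng):
        D = rng.binomial(1, 0.2, 500).astype(float)
        Z = pd.DataFrame({"z": rng.binomial(2, 0.3, 500).astype(float)})
        fit = fit_genetic_share(D, Z, None)
        assert fit.llf >= fit.llnull - 1e-9
        assert fit.s2 >= 0


class TestInstrumentStrength:
    def test_null_lrt_matches_chi_square_reference(self, rng):
        """With uninformative instruments the LRT is chi-square(k) calibrated."""
        k, reps, n = 5, 120, 2_000
        stats = []
        for _ in range(reps):
            D = rng.binomial(1, 0.1, n).astype(float)
            Z = pd.DataFrame(rng.binomial(2, 0.3, (n, k)).astype(float),
                             columns=[f"z{i}" for i in range(k)])
            fit = fit_genetic_share(D, Z, None)
            stats.append(instrument_strength_lrt(fit)[0])
        # upper-tail calibration at the working significance level
        frac = np.mean(np.array(stats) > chi2.ppf(0.95, k))
        assert abs(frac - 0.05) < 0.05

    def test_strong_instruments_give_extreme_lrt(self):
        coh = simulate_cohort(simple_mr_config(50_000, np.log(1.1), theta2=0.05, seed=21))
        fit = fit_genetic_share(coh.exposure, coh.genotypes.dosages, None)
        assert instrument_strength_lrt(fit)[2] < 1e-10


class TestTheta2LowerBound:
    def test_zero_coefficients_give_zero(self, rng):
        D = rng.binomial(1, 0.3, 100).astype(float)
        with pytest.warns(UserWarning):
            fit = fit_genetic_share(D, pd.DataFrame({"z": np.zeros(100)}), None)
        assert estimate_theta2_lower_bound(fit) == 0.0

    def test_recovery_when_all_variants_measured(self):
        coh = simulate_cohort(simple_mr_config(100_000, np.log(1.1), theta2=0.047, seed=22))
        fit = fit_genetic_share(coh.exposure, coh.genotypes.dosages, None)
        assert estimate_theta2_lower_bound(fit) == pytest.approx(0.047, abs=0.01)

    def test_attenuation_when_half_the_share_is_unmeasured(self):
        """Fitting on a subset of causal variants under-states theta^2."""
        hits = 0
        for seed in range(10):
            coh = simulate_cohort(
                simple_mr_config(20_000, 0.0, theta2=0.08, n_instruments=6, seed=30 + seed)
            )
            Z = coh.genotypes.dosages[["iv1", "iv2", "iv3"]]
            fit = fit_genetic_share(coh.exposure, Z, None)
            hits += estimate_theta2_lower_bound(fit) < 0.08
        assert hits >= 9


class TestOutcomeScan:
    def test_matches_direct_log_likelihood_maximisation(self, tiny_binary_fit_data):
        y, X = tiny_binary_fit_data
        Z = pd.DataFrame({"g": X[:, 1]})
        M = pd.DataFrame({"x": X[:, 2]})
        out = outcome_scan(y, Z, M)
        oracle = oracle_poisson_log(y, X)
        assert out.loc["g", "beta"] == pytest.approx(oracle[1], abs=1e-6)

    def test_rare_outcome_recovers_per_allele_rr(self, rng):
        n, rr = 100_000, 1.2
        g = rng.binomial(2, 0.3, n).astype(float)
        risk = 0.02 * rr**g / rr ** (2 * 0.3)
        y = (rng.random(n) < risk).astype(float)
        out = outcome_scan(y, pd.DataFrame({"g": g}), None)
        se = out.loc["g", "se"]
        assert out.loc["g", "beta"] == pytest.approx(np.log(rr), abs=3 * se)

    def test_log_rr_close_to_log_or_for_rare_outcome(self, rng):
        from coarsemr.gwas import logistic_scan
        from coarsemr.containers import GenotypeMatrix

        n = 100_000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.02 * 1.2**g / 1.2**0.6).astype(float)
        log_rr = outcome_scan(y, pd.DataFrame({"g": g}), None).loc["g", "beta"]
        (tab,) = logistic_scan(GenotypeMatrix(pd.DataFrame({"g": g})), y, None, [[]])
        log_or = tab.loc[0, "beta"]
        assert abs(log_rr - log_or) / abs(log_or) < 0.10

    def test_null_scan_unbiased(self, rng):
        betas = []
        for _ in range(200):
            g = rng.binomial(2, 0.3, 2_000).astype(float)
            y = rng.binomial(1, 0.1, 2_000).astype(float)
            betas.append(outcome_scan(y, pd.DataFrame({"g": g}), None).loc["g", "beta"])
        assert abs(np.mean(betas)) < 0.01


class TestWaldRatios:
    @staticmethod
    def _fit_stub(coefs):
        from coarsemr.mr import GeneticShareFit

        snps = list(coefs)
        return GeneticShareFit(
            instruments=snps,
            coef=pd.Series(coefs),
            se=pd.Series(0.01, index=snps),
            cov=pd.DataFrame(np.eye(len(snps)) * 1e-4, index=snps, columns=snps),
            confounder_coef=pd.Series(dtype=float),
            llf=-10.0, llnull=-20.0,
            genetic_share=np.zeros(10), s2=0.05, n=10, converged=True,
        )

    @staticmethod
    def _outcome_stub(snps, beta=0.05, se=0.02):
        return pd.DataFrame({"beta": beta, "se": se, "n": 1000, "converged": True},
                            index=pd.Index(snps, name="snp"))

    def test_theta2_zero_leaves_probit_scale(self):
        fit = self._fit_stub({"a": 0.2, "b": -0.15})
        r = liability_wald_ratios(fit, self._outcome_stub(["a", "b"]), theta2=0.0)
        assert (r["gamma_star"] == r["c"]).all()

    def test_scaling_factor_exact(self):
        fit = self._fit_stub({"a": 0.2, "b": -0.15})
        out = self._outcome_stub(["a", "b"])
        r0 = liability_wald_ratios(fit, out, theta2=0.0)
        r1 = liability_wald_ratios(fit, out, theta2=0.047)
        factor = 1.0 / np.sqrt(1 - 0.047)
        np.testing.assert_allclose(r1["wald"], r0["wald"] * factor, rtol=1e-12)
        np.testing.assert_allclose(r1["wald_se"], r0["wald_se"] * factor, rtol=1e-12)

    def test_magnitude_monotone_in_theta2(self):
        fit = self._fit_stub({"a": 0.2})
        out = self._outcome_stub(["a"])
        mags = [
            abs(liability_wald_ratios(fit, out, theta2=t)["wald"].iloc[0])
            for t in (0.0, 0.047, 0.14, 0.3)
        ]
        assert np.all(np.diff(mags) > 0)

    def test_tiny_coefficient_excluded_with_warning(self):
        fit = self._fit_stub({"a": 0.2, "tiny": 1e-12})
        with pytest.warns(UserWarning, match="unstable"):
            r = liability_wald_ratios(fit, self._outcome_stub(["a", "tiny"]), theta2=0.0)
        assert list(r.index) == ["a"]

    def test_bad_theta2_rejected(self):
        fit = self._fit_stub({"a": 0.2})
        with pytest.raises(ConfigError):
            liability_wald_ratios(fit, self._outcome_stub(["a"]), theta2=1.0)


class TestCochranQAndIvw:
    def test_identical_ratios_are_homogeneous(self):
        r = _ratio_table([(f"s{i}", 0.1, 0.05, 0.2, 0.2, 0.5, 0.25) for i in range(4)])
        het = cochran_q(r)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.p == pytest.approx(1.0)
        assert het.model == "fixed"

    def test_hand_computed_three_ratio_example(self):
        # ratios (0.10, 0.05), (0.20, 0.05), (0.00, 0.10):
        # weights 400, 400, 100 -> b_FE = 120/900 = 2/15; Q = 4 exactly
        r = _ratio_table([
            ("a", np.nan, np.nan, 1, 1, 0.10, 0.05),
            ("b", np.nan, np.nan, 1, 1, 0.20, 0.05),
            ("c", np.nan, np.nan, 1, 1, 0.00, 0.10),
        ])
        het = cochran_q(r)
        assert het.Q == pytest.approx(4.0, rel=1e-12)
        assert het.df == 2
        assert het.p == pytest.approx(np.exp(-2.0), rel=1e-12)
        est = ivw_combine(r, "fixed")
        assert est.estimate == pytest.approx(2.0 / 15.0, rel=1e-12)
        assert est.se == pytest.approx(1.0 / 30.0, rel=1e-12)

    def test_single_ratio_identity(self):
        r = _ratio_table([("a", np.nan, np.nan, 1, 1, 0.095, 0.04)])
        est = ivw_combine(r, "random", theta2=0.047)
        assert est.method == "IVW-FE"  # forced fixed at k = 1
        assert est.estimate == pytest.approx(0.095)
        assert est.rr == pytest.approx(np.exp(0.095))
        assert est.ci_low == pytest.approx(np.exp(0.095 - 1.959963985 * 0.04), rel=1e-6)

    def test_random_equals_fixed_when_q_small(self):
        r = _ratio_table([
            ("a", np.nan, np.nan, 1, 1, 0.10, 0.10),
            ("b", np.nan, np.nan, 1, 1, 0.11, 0.10),
            ("c", np.nan, np.nan, 1, 1, 0.09, 0.10),
        ])
        fe, re = ivw_combine(r, "fixed"), ivw_combine(r, "random")
        assert re.estimate == fe.estimate
        assert re.se == fe.se  # Q <= k-1 -> no inflation

    def test_q_needs_two_ratios_and_ivw_rejects_empty(self):
        one = _ratio_table([("a", np.nan, np.nan, 1, 1, 0.1, 0.05)])
        with pytest.raises(DataError):
            cochran_q(one)
        with pytest.raises(DataError):
            ivw_combine(one.iloc[:0], "fixed")

    def test_q_null_calibration(self, rng):
        """Homogeneous-ratio worlds reject at ~5%."""
        k, reps = 10, 1_000
        hits = 0
        for _ in range(reps):
            se = rng.uniform(0.05, 0.15, k)
            b = 0.1 + rng.normal(0, se)
            r = _ratio_table([(f"s{i}", np.nan, np.nan, 1, 1, b[i], se[i]) for i in range(k)])
            hits += cochran_q(r).p < 0.05
        assert abs(hits / reps - 0.05) < 0.02


class TestPrsMethod:
    def test_estimate_invariant_to_score_rescaling(self, rng):
        n = 4_000
        s = rng.standard_normal(n)
        D = (rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 0.5 * s)))).astype(float)
        Y = (rng.random(n) < 0.10 * np.exp(0.1 * s)).astype(float)
        b1, se1, c1 = score_associations(D, Y, s)
        b2, se2, c2 = score_associations(D, Y, 2.5 * s)
        assert b1 / c1 == pytest.approx(b2 / c2, rel=1e-6)
        assert se1 / abs(c1) == pytest.approx(se2 / abs(c2), rel=1e-6)

    def test_prs_agrees_with_ivw_under_homogeneity(self):
        coh = simulate_cohort(simple_mr_config(30_000, np.log(1.10), seed=40))
        Z = coh.genotypes.dosages
        fit = fit_genetic_share(coh.exposure, Z, None)
        out = outcome_scan(coh.outcome, Z, None)
        ratios = liability_wald_ratios(fit, out, 0.047)
        ivw = ivw_combine(ratios, "fixed", 0.047)
        prs = prs_method(coh.exposure, coh.outcome, Z, None, 0.047, seed=40)
        assert prs.rr == pytest.approx(ivw.rr, abs=0.05)

    def test_prs_seed_determinism(self):
        coh = simulate_cohort(simple_mr_config(5_000, np.log(1.2), seed=41))
        Z = coh.genotypes.dosages
        a = prs_method(coh.exposure, coh.outcome, Z, None, 0.047, seed=5)
        b = prs_method(coh.exposure, coh.outcome, Z, None, 0.047, seed=5)
        assert a.estimate == b.estimate and a.se == b.se

    def test_too_few_folds_rejected(self):
        coh = simulate_cohort(simple_mr_config(1_000, 0.0, seed=42))
        with pytest.raises(ConfigError):
            prs_method(coh.exposure, coh.outcome, coh.genotypes.dosages, None, 0.0, n_folds=1)


class TestSensitivitySweep:
    def test_grid_layout_and_flagging(self):
        coh = simulate_cohort(simple_mr_config(20_000, np.log(1.15), seed=50))
        sweep = sensitivity_sweep(
            coh.exposure, coh.outcome, coh.genotypes.dosages, None,
            [0.04, 0.07, 0.14], seed=50,
        )
        t = sweep.table
        # 3 grid points + estimated theta2, two methods each
        assert len(t) == 2 * 4
        assert t["is_estimated"].sum() == 2
        assert set(t["method"]) == {"IVW-FE", "PRS"} or set(t["method"]) == {"IVW-RE", "PRS"}
        for method in t["method"].unique():
            sub = t[t.method == method].sort_values("theta2")
            assert np.all(np.diff(np.abs(sub["log_rr"])) > 0)

    def test_empty_grid_rejected(self):
        coh = simulate_cohort(simple_mr_config(1_000, 0.0, seed=51))
        with pytest.raises(ConfigError):
            sensitivity_sweep(coh.exposure, coh.outcome, coh.genotypes.dosages, None, [])


class TestConfounderAdjustmentConsistency:
    def test_adjusted_and_unadjusted_agree_when_instruments_clean(self, bidir_cohort):
        """Instruments independent of M: adjustment must not move the estimate."""
        Z = bidir_cohort.genotypes.dosages[[f"exp_iv{j}" for j in (1, 2, 3, 4)]]
        M = bidir_cohort.phenotypes[["age", "sex", "bmi", "creatinine"]]
        D, Y = bidir_cohort.exposure, bidir_cohort.outcome
        est = {}
        for label, m in (("unadj", None), ("adj", M)):
            fit = fit_genetic_share(D, Z, m)
            out = outcome_scan(Y, Z, m)
            ratios = liability_wald_ratios(fit, out, 0.09)
            est[label] = ivw_combine(ratios, "fixed", 0.09)
        assert est["adj"].estimate == pytest.approx(
            est["unadj"].estimate, abs=1.0 * est["unadj"].se
        )
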