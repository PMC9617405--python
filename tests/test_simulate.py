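"""Simulator tests: threshold calibration, determinism, variance control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from coarsemr.containers import ConfigError, DataError
from coarsemr.qc import hwe_exact_test
from coarsemr.simulate import (
    ConfounderSpec,
    SimulationConfig,
    SnpSpec,
    bidirectional_test_config,
    calibrate_outcome_baseline,
    calibrate_threshold,
    expected_outcome_prevalence,
    simple_mr_config,
    simulate_cohort,
)


class TestCalibrateThreshold:
    def test_symmetric_liabilities_target_half_gives_median(self):
        rng = np.random.default_rng(0)
        l = rng.standard_normal(10_001)
        tau = calibrate_threshold(l, 0.5)
        assert tau == pytest.approx(np.median(l), abs=1e-12)

    def test_gout_prevalence_hit_on_standard_normal_liabilities(self):
        rng = np.random.default_rng(1)
        l = rng.standard_normal(100_000)
        tau = calibrate_threshold(l, 0.0368)
        assert abs((l > tau).mean() - 0.0368) < 0.002

    def test_threshold_monotone_in_target(self):
        rng = np.random.default_rng(2)
        l = rng.standard_normal(5_000)
        assert calibrate_threshold(l, 0.01) > calibrate_threshold(l, 0.10)

    def test_degenerate_liabilities_rejected(self):
        with pytest.raises(DataError, match="not identifiable"):
            calibrate_threshold(np.ones(100), 0.1)


class TestSimulateCohort:
    def test_seed_determinism(self):
        cfg = simple_mr_config(2_000, np.log(1.1), seed=11, missing_genotype_rate=0.02)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.true_parameters["tau"] == b.true_parameters["tau"]

    def test_different_seed_changes_cohort(self):
        a = simulate_cohort(simple_mr_config(2_000, 0.0, seed=1))
        b = simulate_cohort(simple_mr_config(2_000, 0.0, seed=2))
        assert not a.genotypes.dosages.equals(b.genotypes.dosages)

    def test_exposure_is_liability_threshold_exactly(self):
        coh = simulate_cohort(simple_mr_config(5_000, np.log(1.1), seed=3))
        L = coh.true_parameters["liability"]
        tau = coh.true_parameters["tau"]
        np.testing.assert_array_equal(coh.exposure, (L > tau).astype(int))

    def test_prevalences_within_sampling_error(self):
        cfg = bidirectional_test_config(n_individuals=50_000, seed=5)
        coh = simulate_cohort(cfg)
        for realized, target in [
            (coh.true_parameters["realized_exposure_prevalence"], 0.0368),
            (coh.true_parameters["realized_outcome_prevalence"], 0.1352),
        ]:
            se = np.sqrt(target * (1 - target) / cfg.n_individuals)
            assert abs(realized - target) < 3 * se

    def test_analytic_outcome_prevalence_matches_empirical(self):
        cfg = bidirectional_test_config(n_individuals=50_000, seed=9)
        assert expected_outcome_prevalence(cfg) == pytest.approx(0.1352, abs=1e-9)

    def test_missingness_rate_realised(self):
        cfg = simple_mr_config(20_000, 0.0, seed=4, missing_genotype_rate=0.05)
        coh = simulate_cohort(cfg)
        frac = coh.genotypes.dosages.isna().to_numpy().mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_excessive_risk_rejected_naming_parameters(self):
        cfg = simple_mr_config(5_000, np.log(1.1), seed=6)
        hot = cfg.model_copy(update={"outcome_baseline_risk": 0.9})
        with pytest.raises(ConfigError, match="outcome_baseline_risk"):
            simulate_cohort(hot)


class TestConfigValidation:
    def test_theta2_without_liability_snps_rejected(self):
        with pytest.raises(ValueError, match="liability effect"):
            SimulationConfig(
                n_individuals=100,
                snps=[SnpSpec(id="a", maf=0.3)],
                theta2=0.05,
                exposure_prevalence=0.1,
                outcome_baseline_risk=0.1,
            )

    def test_overfull_liability_variance_rejected(self):
        conf = ConfounderSpec(name="x", distribution="normal", effect_liability=0.9)
        with pytest.raises(ValueError, match="environmental variance"):
            SimulationConfig(
                n_individuals=100,
                snps=[SnpSpec(id="a", maf=0.3, gamma_liability=1.0)],
                theta2=0.3,
                exposure_prevalence=0.1,
                outcome_baseline_risk=0.1,
                confounders=[conf],
            )

    def test_pleiotropy_on_bernoulli_confounder_rejected(self):
        conf = ConfounderSpec(name="sex", distribution="bernoulli", p=0.4)
        with pytest.raises(ValueError, match="bernoulli"):
            SimulationConfig(
                n_individuals=100,
                snps=[
                    SnpSpec(id="a", maf=0.3, gamma_liability=1.0,
                            pleiotropy_confounder="sex", pleiotropy_confounder_effect=0.1)
                ],
                theta2=0.05,
                exposure_prevalence=0.1,
                outcome_baseline_risk=0.1,
                confounders=[conf],
            )


class TestVarianceControl:
    def test_heritability_recovered_by_regression_of_liability_on_genotypes(self):
        """R^2 of true liability on the instruments tracks configured theta^2."""
        cfg = simple_mr_config(50_000, np.log(1.1), theta2=0.047, seed=8)
        coh = simulate_cohort(cfg)
        L = coh.true_parameters["liability"]
        Z = coh.genotypes.dosages.to_numpy()
        X = np.column_stack([np.ones(len(L)), Z])
        resid = L - X @ np.linalg.lstsq(X, L, rcond=None)[0]
        r2 = 1 - resid.var() / L.var()
        assert r2 == pytest.approx(0.047, abs=0.01)

    def test_simulated_genotypes_conform_to_hwe(self):
        """Exact-test p-values over 500 simulated SNPs are ~uniform."""
        cfg = SimulationConfig(
            n_individuals=10_000,
            snps=[SnpSpec(id=f"s{i}", maf=0.05 + 0.4 * (i / 499)) for i in range(500)],
            theta2=0.0,
            exposure_prevalence=0.1,
            outcome_baseline_risk=0.1,
            seed=12,
        )
        coh = simulate_cohort(cfg)
        counts = coh.genotypes.genotype_counts()
        ps = [
            hwe_exact_test(int(r.n_hom_ref), int(r.n_het), int(r.n_hom_alt))
            for _, r in counts.iterrows()
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_outcome_baseline_calibration_is_exact_in_expectation(self):
        cfg = simple_mr_config(5_000, np.log(1.2), seed=13)
        recal = calibrate_outcome_baseline(cfg, 0.08)
        assert expected_outcome_prevalence(recal) == pytest.approx(0.08, rel=1e-9)
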