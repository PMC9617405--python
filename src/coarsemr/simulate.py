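"""Synthetic cohorts with the exact causal structure the estimator assumes.

The generative model mirrors the analysis DAG.  Instruments Z_j are
independent Binomial(2, maf_j) allele counts (Hardy-Weinberg).  Each
measured confounder has a standardised latent score (unit-variance normal,
or a standardised Bernoulli for binary traits); optional pleiotropic SNPs
may shift a score additively per allele.  Exposure liability is

    L = sum_j gamma_j (Z_j - 2 maf_j)  +  alpha' M_score  +  V,

with V normal and gamma internally rescaled so Var(genetic share) equals
the configured heritability theta^2 and Var(L) = 1.  The binary exposure
is D = 1{L > tau} with tau the empirical liability quantile matching the
target prevalence.  The binary outcome follows a log-linear (relative
risk) model

    P(Y=1) = exp( log r0 + beta_L * L + delta' M_score + sum_j pi_j Z_j ),

where pi_j are direct (exclusion-restriction-violating) SNP effects.  Any
realised risk >= 1 aborts the simulation naming the offending parameters.

Defaults in :func:`taiwan_biobank_like_config` emulate a large East-Asian
biobank cohort: n = 88,347, gout prevalence 3.68%, hypertension
prevalence 13.52%, gout liability heritability 0.047 carried by five
genome-wide-significant SNPs (one of which — an rs671/ALDH2 analogue — is
pleiotropic), ten hypertension instruments, and age/sex/BMI/creatinine
confounders matched to the cohort's published margins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .containers import ConfigError, DataError, GenotypeMatrix

__all__ = [
    "SnpSpec",
    "ConfounderSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "calibrate_threshold",
    "simulate_cohort",
    "expected_outcome_prevalence",
    "calibrate_outcome_baseline",
    "taiwan_biobank_like_config",
    "bidirectional_test_config",
    "simple_mr_config",
]


class SnpSpec(BaseModel):
    """One simulated SNP: frequency, liability effect, pleiotropy knobs.

    ``gamma_liability`` is a *relative* loading; the simulator rescales all
    loadings jointly so the genetic-share variance equals theta^2.
    ``pleiotropy_outcome`` is a direct log-RR per allele on the outcome;
    ``pleiotropy_confounder`` shifts the named confounder's standardised
    score by ``pleiotropy_confounder_effect`` per allele (two distinct
    pleiotropic pathways, selectable independently).
    """

    id: str
    maf: float = Field(gt=0.0, lt=1.0)
    gamma_liability: float = 0.0
    pleiotropy_outcome: float = 0.0
    pleiotropy_confounder: Optional[str] = None
    pleiotropy_confounder_effect: float = 0.0


class ConfounderSpec(BaseModel):
    """A measured confounder with effects on liability and outcome.

    Effects are per standard deviation of the confounder's standardised
    score (for lognormal confounders, the underlying normal), keeping the
    liability variance decomposition and the outcome normalising constant
    analytic.
    """

    name: str
    distribution: Literal["normal", "bernoulli", "lognormal"]
    mean: float = 0.0  # normal: mean; lognormal: meanlog
    sd: float = 1.0  # normal: sd; lognormal: sdlog
    p: float = 0.5  # bernoulli only
    effect_liability: float = 0.0
    effect_outcome: float = 0.0


class SimulationConfig(BaseModel):
    """Full description of one synthetic cohort (the 'stated world')."""

    n_individuals: int = Field(ge=10)
    snps: list[SnpSpec]
    theta2: float = Field(ge=0.0, lt=1.0)
    exposure_prevalence: float = Field(gt=0.0, lt=1.0)
    outcome_baseline_risk: float = Field(gt=0.0, lt=1.0)
    beta_liability: float = 0.0
    confounders: list[ConfounderSpec] = Field(default_factory=list)
    missing_genotype_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    @model_validator(mode="after")
    def _check_structure(self) -> "SimulationConfig":
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in simulation config")
        conf_names = {c.name for c in self.confounders}
        if len(conf_names) != len(self.confounders):
            raise ValueError("duplicate confounder names")
        for s in self.snps:
            if s.pleiotropy_confounder is not None:
                if s.pleiotropy_confounder not in conf_names:
                    raise ValueError(
                        f"SNP {s.id}: unknown pleiotropy target {s.pleiotropy_confounder!r}"
                    )
                target = next(c for c in self.confounders if c.name == s.pleiotropy_confounder)
                if target.distribution == "bernoulli":
                    raise ValueError(
                        f"SNP {s.id}: additive score shift undefined for a "
                        f"bernoulli confounder ({target.name})"
                    )
        if self.theta2 > 0 and not any(s.gamma_liability != 0 for s in self.snps):
            raise ValueError("theta2 > 0 requires at least one SNP with a liability effect")
        dec = _liability_decomposition(self)
        if dec["sigma_v2"] <= 1e-6:
            raise ValueError(
                "environmental variance would be non-positive: reduce theta2 "
                "or the confounder liability effects "
                f"(theta2={self.theta2}, confounder share={dec['var_conf']:.4f})"
            )
        return self


def _liability_decomposition(config: SimulationConfig) -> dict:
    """Analytic variance bookkeeping implied by the config.

    Returns the rescaled per-SNP liability loadings (Var(G) = theta2
    exactly), the confounder share of liability variance, the G-confounder
    covariance induced by via-confounder pleiotropy, and the environmental
    variance sigma_v2 that tops liability variance up to 1.
    """
    mafs = np.array([s.maf for s in config.snps])
    gammas = np.array([s.gamma_liability for s in config.snps], dtype=float)
    snp_var = 2.0 * mafs * (1.0 - mafs)
    raw = float(np.sum(gammas**2 * snp_var))
    if config.theta2 > 0:
        scale = np.sqrt(config.theta2 / raw)
    else:
        scale = 0.0
    g_scaled = gammas * scale

    alphas = np.array([c.effect_liability for c in config.confounders])
    # u_j: combined per-allele shift of alpha' M_score from via-confounder pleiotropy
    u = np.zeros(len(config.snps))
    for j, s in enumerate(config.snps):
        if s.pleiotropy_confounder is not None:
            m = next(i for i, c in enumerate(config.confounders) if c.name == s.pleiotropy_confounder)
            u[j] = alphas[m] * s.pleiotropy_confounder_effect
    var_conf = float(np.sum(alphas**2) + np.sum(u**2 * snp_var))
    cov_gm = float(np.sum(g_scaled * u * snp_var))
    sigma_v2 = 1.0 - config.theta2 - var_conf - 2.0 * cov_gm
    return {
        "gamma_scaled": dict(zip([s.id for s in config.snps], g_scaled)),
        "var_conf": var_conf,
        "cov_gm": cov_gm,
        "sigma_v2": sigma_v2,
    }


@dataclass
class SyntheticCohort:
    """A realised cohort plus every true parameter needed for oracles."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # indexed by sample id
    true_parameters: dict

    @property
    def exposure(self) -> np.ndarray:
        return self.phenotypes[self.true_parameters["exposure_name"]].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.phenotypes[self.true_parameters["outcome_name"]].to_numpy()

    def confounder_table(self) -> pd.DataFrame:
        names = self.true_parameters["confounder_names"]
        return self.phenotypes[names]


def calibrate_threshold(liabilities: np.ndarray, target_prevalence: float) -> float:
    """Empirical liability threshold realising a target prevalence.

    Returns the (1 - target) empirical quantile, so the fraction of
    liabilities strictly above it is the closest achievable to the target
    (within 1/n for continuous liabilities).
    """
    l = np.asarray(liabilities, dtype=float)
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigError(f"target prevalence {target_prevalence} outside (0, 1)")
    if l.size == 0 or np.ptp(l) == 0.0:
        raise DataError("degenerate (constant) liabilities: threshold not identifiable")
    return float(np.quantile(l, 1.0 - target_prevalence))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the configured generative model.

    Identical configs (including seed) give bit-identical cohorts.  The
    delivered genotype matrix has missing calls injected completely at
    random at ``missing_genotype_rate``; liability uses the true calls.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    p = len(config.snps)
    mafs = np.array([s.maf for s in config.snps])
    dec = _liability_decomposition(config)
    g_scaled = np.array([dec["gamma_scaled"][s.id] for s in config.snps])

    Z = rng.binomial(2, mafs, size=(n, p)).astype(float)
    Zc = Z - 2.0 * mafs

    # confounder scores: standardised base draw plus pleiotropic shifts
    scores = np.zeros((n, len(config.confounders)))
    raw_values = {}
    base_draws = {}
    for m, c in enumerate(config.confounders):
        if c.distribution == "bernoulli":
            b = (rng.random(n) < c.p).astype(float)
            s = (b - c.p) / np.sqrt(c.p * (1.0 - c.p))
            base_draws[c.name] = b
        else:
            s = rng.standard_normal(n)
        scores[:, m] = s
    for j, spec in enumerate(config.snps):
        if spec.pleiotropy_confounder is not None:
            m = next(i for i, c in enumerate(config.confounders) if c.name == spec.pleiotropy_confounder)
            scores[:, m] = scores[:, m] + spec.pleiotropy_confounder_effect * Zc[:, j]
    for m, c in enumerate(config.confounders):
        if c.distribution == "normal":
            raw_values[c.name] = c.mean + c.sd * scores[:, m]
        elif c.distribution == "lognormal":
            raw_values[c.name] = np.exp(c.mean + c.sd * scores[:, m])
        else:
            raw_values[c.name] = base_draws[c.name]

    alphas = np.array([c.effect_liability for c in config.confounders])
    deltas = np.array([c.effect_outcome for c in config.confounders])
    G = Zc @ g_scaled
    V = rng.normal(0.0, np.sqrt(dec["sigma_v2"]), size=n)
    L = G + (scores @ alphas if len(config.confounders) else 0.0) + V

    tau = calibrate_threshold(L, config.exposure_prevalence)
    D = (L > tau).astype(int)

    pis = np.array([s.pleiotropy_outcome for s in config.snps])
    log_risk = (
        np.log(config.outcome_baseline_risk)
        + config.beta_liability * L
        + (scores @ deltas if len(config.confounders) else 0.0)
        + Z @ pis
    )
    risk = np.exp(log_risk)
    if risk.max() >= 1.0:
        raise ConfigError(
            f"realised outcome risk reaches {risk.max():.3f} >= 1 under "
            f"outcome_baseline_risk={config.outcome_baseline_risk}, "
            f"beta_liability={config.beta_liability}; lower the baseline "
            "risk or the log-linear effects"
        )
    Y = (rng.random(n) < risk).astype(int)

    delivered = Z.copy()
    if config.missing_genotype_rate > 0:
        miss = rng.random((n, p)) < config.missing_genotype_rate
        delivered[miss] = np.nan

    sample_ids = [f"S{i:06d}" for i in range(n)]
    snp_ids = [s.id for s in config.snps]
    meta = pd.DataFrame(
        {
            "chromosome": ["1"] * p,
            "position": np.arange(1, p + 1) * 1000,
            "effect_allele": ["A"] * p,
            "other_allele": ["G"] * p,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    genotypes = GenotypeMatrix(
        pd.DataFrame(delivered, index=sample_ids, columns=snp_ids), meta
    )
    pheno = pd.DataFrame(
        {config.exposure_name: D, config.outcome_name: Y, **raw_values},
        index=pd.Index(sample_ids, name="IID"),
    )
    true_parameters = {
        "config": config.model_dump(),
        "exposure_name": config.exposure_name,
        "outcome_name": config.outcome_name,
        "confounder_names": [c.name for c in config.confounders],
        "gamma_scaled": dec["gamma_scaled"],
        "sigma_v2": dec["sigma_v2"],
        "tau": tau,
        "realized_exposure_prevalence": float(D.mean()),
        "realized_outcome_prevalence": float(Y.mean()),
        "liability": L,  # kept for oracle checks; not written to disk
    }
    return SyntheticCohort(genotypes=genotypes, phenotypes=pheno, true_parameters=true_parameters)


# ---------------------------------------------------------------------------
# analytic outcome-prevalence calibration
# ---------------------------------------------------------------------------
def expected_outcome_prevalence(config: SimulationConfig) -> float:
    """Closed-form E[P(Y=1)] under the log-linear outcome model.

    Uses moment generating functions of the independent liability
    components: normal scores and V contribute exp(t^2/2) factors,
    standardised Bernoulli scores their exact mgf, and each SNP a
    Binomial(2, maf) mgf with its combined loading on the log risk.
    """
    dec = _liability_decomposition(config)
    bl = config.beta_liability
    total = np.log(config.outcome_baseline_risk)
    total += 0.5 * bl**2 * dec["sigma_v2"]
    for c in config.confounders:
        t = bl * c.effect_liability + c.effect_outcome
        if c.distribution == "bernoulli":
            s = np.sqrt(c.p * (1 - c.p))
            mgf = (1 - c.p) * np.exp(-t * c.p / s) + c.p * np.exp(t * (1 - c.p) / s)
            total += np.log(mgf)
        else:
            total += 0.5 * t**2
    for spec in config.snps:
        g = dec["gamma_scaled"][spec.id]
        u = 0.0
        if spec.pleiotropy_confounder is not None:
            c = next(cc for cc in config.confounders if cc.name == spec.pleiotropy_confounder)
            u = (bl * c.effect_liability + c.effect_outcome) * spec.pleiotropy_confounder_effect
        a = bl * g + spec.pleiotropy_outcome + u
        centred = -(2.0 * spec.maf) * (bl * g + u)  # pi terms are not centred
        total += centred + 2.0 * np.log((1 - spec.maf) + spec.maf * np.exp(a))
    return float(np.exp(total))


def calibrate_outcome_baseline(config: SimulationConfig, target_prevalence: float) -> SimulationConfig:
    """Rescale the log-linear intercept so E[P(Y=1)] hits the target."""
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigError(f"target prevalence {target_prevalence} outside (0, 1)")
    current = expected_outcome_prevalence(config)
    new_r0 = config.outcome_baseline_risk * target_prevalence / current
    return config.model_copy(update={"outcome_baseline_risk": new_r0})


# ---------------------------------------------------------------------------
# bundled configurations
# ---------------------------------------------------------------------------
def taiwan_biobank_like_config(
    seed: int = 2022, n_individuals: int = 88_347, include_null_snps: bool = True
) -> SimulationConfig:
    """Default cohort emulating the Taiwan Biobank gout/hypertension design.

    SNP ids echo real gout/urate and blood-pressure loci but every value
    here is synthetic.  Gout carries theta^2 = 0.047 over five instruments
    (the rs671 analogue is pleiotropic: a direct outcome effect plus a
    creatinine shift so the confounder screen flags it); hypertension is
    driven by ten direct-effect SNPs; the causal liability effect of gout
    on hypertension is log(1.10) per liability SD.  Confounder margins
    follow the published cohort table (age 51.1 +/- 11.1, 31.9% male, BMI
    24.25 +/- 3.83, creatinine mean 0.71 lognormal).
    """
    gout = [
        SnpSpec(id="rs2231142", maf=0.28, gamma_liability=1.00),
        SnpSpec(
            id="rs671",
            maf=0.24,
            gamma_liability=0.85,
            pleiotropy_outcome=float(np.log(1.03)),
            pleiotropy_confounder="creatinine",
            pleiotropy_confounder_effect=0.05,
        ),
        SnpSpec(id="rs3775948", maf=0.35, gamma_liability=0.70),
        SnpSpec(id="rs1260326", maf=0.22, gamma_liability=0.60),
        SnpSpec(id="rs16890979", maf=0.42, gamma_liability=0.55),
    ]
    htn_rr = [1.12, 1.10, 1.14, 1.10, 1.12, 1.10, 1.14, 1.11, 1.10, 1.12]
    htn_maf = [0.30, 0.35, 0.18, 0.40, 0.25, 0.33, 0.20, 0.28, 0.45, 0.38]
    htn = [
        SnpSpec(id=f"rs_htn{i+1:02d}", maf=m, pleiotropy_outcome=float(np.log(r)))
        for i, (m, r) in enumerate(zip(htn_maf, htn_rr))
    ]
    nulls = []
    if include_null_snps:
        null_mafs = np.linspace(0.06, 0.48, 35)
        nulls = [SnpSpec(id=f"rs_null{i+1:03d}", maf=float(m)) for i, m in enumerate(null_mafs)]
    confs = [
        ConfounderSpec(
            name="age", distribution="normal", mean=51.10, sd=11.12,
            effect_liability=0.10, effect_outcome=0.30,
        ),
        ConfounderSpec(
            name="sex", distribution="bernoulli", p=0.319,  # 1 = male
            effect_liability=0.15, effect_outcome=0.10,
        ),
        ConfounderSpec(
            name="bmi", distribution="normal", mean=24.25, sd=3.83,
            effect_liability=0.15, effect_outcome=0.10,
        ),
        ConfounderSpec(  # meanlog/sdlog matched to mean 0.71, sd ~0.31
            name="creatinine", distribution="lognormal", mean=-0.4297, sd=0.4177,
            effect_liability=0.10, effect_outcome=0.05,
        ),
    ]
    config = SimulationConfig(
        n_individuals=n_individuals,
        snps=gout + htn + nulls,
        theta2=0.047,
        exposure_prevalence=0.0368,
        outcome_baseline_risk=0.1352,  # recalibrated below
        beta_liability=float(np.log(1.10)),
        confounders=confs,
        missing_genotype_rate=0.01,
        seed=seed,
        exposure_name="gout",
        outcome_name="hypertension",
    )
    return calibrate_outcome_baseline(config, 0.1352)


def bidirectional_test_config(
    n_individuals: int = 20_000,
    seed: int = 0,
    beta_liability: float = float(np.log(1.25)),
    n_null_snps: int = 8,
) -> SimulationConfig:
    """Forward-only causal world sized for fast end-to-end pipeline runs.

    Four strong exposure instruments (theta^2 = 0.09, chosen so each
    clears genome-wide significance at n = 20,000 with 3.7% prevalence),
    five strong direct-effect outcome instruments (per-allele RR 1.20),
    null SNPs, and mild measured confounders.  The exposure liability
    causes the outcome (default RR 1.25 per SD); nothing causes the
    exposure except its own liability — so a bidirectional analysis
    should reject the null forward and retain it in reverse.  Effect
    sizes are kept moderate so the log-linear risks stay below 1 across
    the realised tail even at n = 100,000.
    """
    exposure_ivs = [
        SnpSpec(id=f"exp_iv{j+1}", maf=m, gamma_liability=1.0)
        for j, m in enumerate([0.30, 0.25, 0.35, 0.20])
    ]
    outcome_ivs = [
        SnpSpec(id=f"out_iv{j+1}", maf=m, pleiotropy_outcome=float(np.log(1.20)))
        for j, m in enumerate([0.30, 0.25, 0.35, 0.40, 0.22])
    ]
    nulls = [
        SnpSpec(id=f"null{j+1:02d}", maf=float(m))
        for j, m in enumerate(np.linspace(0.10, 0.45, n_null_snps))
    ]
    confs = [
        ConfounderSpec(name="age", distribution="normal", mean=51.1, sd=11.1,
                       effect_liability=0.10, effect_outcome=0.10),
        ConfounderSpec(name="sex", distribution="bernoulli", p=0.319,
                       effect_liability=0.10, effect_outcome=0.10),
        ConfounderSpec(name="bmi", distribution="normal", mean=24.25, sd=3.83,
                       effect_liability=0.05, effect_outcome=0.05),
        ConfounderSpec(name="creatinine", distribution="lognormal", mean=-0.4297, sd=0.4177,
                       effect_liability=0.05, effect_outcome=0.05),
    ]
    config = SimulationConfig(
        n_individuals=n_individuals,
        snps=exposure_ivs + outcome_ivs + nulls,
        theta2=0.09,
        exposure_prevalence=0.0368,
        outcome_baseline_risk=0.1352,
        beta_liability=beta_liability,
        confounders=confs,
        missing_genotype_rate=0.005,
        seed=seed,
        exposure_name="gout",
        outcome_name="hypertension",
    )
    return calibrate_outcome_baseline(config, 0.1352)


def simple_mr_config(
    n_individuals: int,
    beta_liability: float,
    theta2: float = 0.047,
    n_instruments: int = 4,
    seed: int = 0,
    exposure_prevalence: float = 0.0368,
    outcome_prevalence: float = 0.1352,
    missing_genotype_rate: float = 0.0,
) -> SimulationConfig:
    """Minimal valid-instrument world: no confounders, no pleiotropy.

    Used for parameter-recovery and calibration studies where the causal
    effect must be the only systematic signal.
    """
    mafs = [0.30, 0.25, 0.35, 0.20, 0.40, 0.28, 0.33, 0.22][:n_instruments]
    if len(mafs) < n_instruments:
        mafs = list(np.linspace(0.15, 0.45, n_instruments))
    snps = [
        SnpSpec(id=f"iv{j+1}", maf=float(m), gamma_liability=1.0) for j, m in enumerate(mafs)
    ]
    config = SimulationConfig(
        n_individuals=n_individuals,
        snps=snps,
        theta2=theta2,
        exposure_prevalence=exposure_prevalence,
        outcome_baseline_risk=outcome_prevalence,
        beta_liability=beta_liability,
        confounders=[],
        missing_genotype_rate=missing_genotype_rate,
        seed=seed,
    )
    return calibrate_outcome_baseline(config, outcome_prevalence)
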