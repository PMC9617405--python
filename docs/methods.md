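# Methods

## The problem

Mendelian randomisation (MR) uses genetic variants as instrumental
variables to estimate the causal effect of an exposure on an outcome.
Standard MR assumes a continuous exposure with linear effects.  Many
clinically decisive exposures — a gout diagnosis, a hypertension
diagnosis — are binary, and applying continuous-exposure MR to them
yields causal effects that are at best partially identified.  This
package implements MR with *coarsened exposures*: the binary disease
state `D` is treated as a thresholded observation of a latent continuous
liability `L` (the Falconer model), and the causal estimand is the
relative risk of the outcome per one standard deviation of `L`.

## Model

Liability decomposes as

```
L = G + alpha' M + V,        Var(L) = 1,
G = sum_j gamma_j Z_j        (genetic share over instruments Z_j),
V ~ Normal(0, sigma_V^2)     (environmental share),
D = 1{L > tau}.
```

`M` are measured confounders.  Because `V` is normal, maximum-likelihood
probit regression of `D` on the instruments (plus `M`) identifies
`c_j = gamma_j / sigma_V` — the per-allele liability effect in units of
the *residual* SD.  Writing `theta^2` for the fraction of liability
variance that is genetic (liability-scale heritability), the residual SD
is `sqrt(1 - theta^2)` when the instruments span the genetic share, so

```
gamma*_j = c_j * sqrt(1 - theta^2)
```

converts probit coefficients to the total-liability SD scale.  The
binary outcome follows a log-linear (relative-risk) model, so the
per-instrument outcome association `beta_Yj` (log-RR per allele) and the
Wald ratio

```
b_j = beta_Yj / gamma*_j
```

estimate the causal log-RR per liability SD.  Ratios are combined by
inverse-variance weighting; Cochran's Q (chi-square, k−1 df) selects
fixed effects when p ≥ 0.05 and random effects (multiplicative SE
inflation by `sqrt(max(1, Q/(k−1)))`) otherwise.  A polygenic risk score
with 10-fold cross-validated logistic weights serves as an independent
single-composite-instrument estimator of the same quantity; out-of-fold
scoring stands in for the independent weight-training dataset a single
biobank cannot provide.

### Instrument strength

The Cragg–Donald F statistic is undefined for a binary exposure standing
in for a latent trait, so instrument strength is assessed by a
likelihood-ratio test that all instrument coefficients in the probit
liability regression are zero (chi-square, k df).  A large LRT supports
— but cannot prove — that the genetic share is composed of relevant
instruments.

### The sensitivity parameter theta^2

`theta^2` is not identified by the instruments alone.  The variance
`s^2` of the fitted genetic share `sum_j c_j Z_j` (residual scale) gives
the lower bound `theta2_hat = s^2 / (s^2 + 1)`, exact when the measured
instruments carry the whole genetic share and an under-estimate
otherwise (both behaviours are verified by simulation in the test
suite).  All causal estimates are therefore swept over a user grid of
`theta^2` values — defaults `{0.04, 0.07, 0.14}` in the gout-to-
hypertension direction and `{0.01, 0.07, 0.14, 0.21}` in the reverse,
ceilings taken from published SNP heritabilities of urate and blood
pressure — with the data-estimated bound flagged in the output.  Only
the deterministic `sqrt(1 - theta^2)` rescaling varies across the grid;
`|log RR|` is strictly increasing in `theta^2`, so the sweep shows
whether conclusions can flip within the plausible heritability range.
Estimation uncertainty in `theta2_hat` is expressed through the sweep,
not propagated into standard errors.

## Pipeline

Per causal direction: (1) SNP QC — call rate ≤ 0.1 missing, MAF ≥ 0.01,
HWE exact test in controls at p ≥ 1e-6; (2) per-SNP logistic GWAS under
three covariate scenarios (unadjusted; age + sex; age + sex + BMI),
instruments = SNPs at p < 5e-8 in *every* scenario, then greedy LD
pruning at r² < 0.001 on dosage correlations; (3) an instrument-
confounder independence screen — chi-square for categorical confounders,
Spearman for continuous, BH-FDR adjusted jointly, instruments with any
adjusted p < 0.05 removed; (4) liability MR in a 2×2 grid of scenario
cells: with/without confounder adjustment crossed with before/after
screen removal.  When the screen removes nothing the two removal arms
coincide exactly.

## Tunable parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `max_missing_rate` | 0.1 | proportion | array-QC convention |
| `hwe_p_min` | 1e-6 | p-value | stringent filter for genotyping error |
| `maf_min` | 0.01 | frequency | rare variants are weak, unstable IVs |
| `gwas_p_threshold` | 5e-8 | p-value | genome-wide significance |
| `r2_threshold` | 0.001 | squared correlation | near-independence of IVs |
| `screen_alpha` | 0.05 | FDR-adjusted p | confounder-association removal |
| `prs_folds` | 10 | folds | bias/variance balance for CV weights |
| `theta2` grids | see above | variance fraction | published heritability ceilings |

## Numerical choices

- Log-linear outcome fits use a Poisson working likelihood with HC0
  sandwich SEs: consistent for the log-RR and far more stable than
  log-binomial ML (available via `family="log-binomial"`, which falls
  back to Poisson on non-convergence).
- Ratio SEs are first-order delta method, ignoring uncertainty in `c_j`;
  with instruments at genome-wide significance the first stage is strong
  and CI coverage is nominal (checked by simulation at the design of the
  recovery study).
- Non-converged logistic scans retry with a small ridge penalty
  (targets separation at low MAF) and are flagged, never dropped.
- Instruments with `|c_j| < 1e-8` give unstable ratios and are excluded
  from the ratio table with a warning.
- Zero-variance instrument columns get `c_j = 0` exactly rather than
  entering a singular design.
- HWE exact p sums all heterozygote configurations with probability at
  most the observed one (relative tie tolerance 1e-12); pruning ties are
  broken by GWAS p, then genomic position, then SNP id.
- Missing dosages are mean-imputed inside multi-SNP fits (probit, PRS)
  and handled complete-case in per-SNP scans.
- Cochran's Q is invariant to `theta^2` (numerator and weights rescale
  identically), so the fixed/random choice is made once per cell.

## The synthetic-cohort generator

No individual-level biobank data can ship with the package, so every
stage is exercised against a generator that draws cohorts from exactly
the model above: independent Binomial(2, maf) genotypes (hence
Hardy–Weinberg by construction), configurable confounders with analytic
variance bookkeeping, liability rescaled so `Var(G) = theta^2` and
`Var(L) = 1`, threshold `tau` set to the empirical liability quantile of
the target prevalence, and a log-linear outcome whose intercept is
calibrated in closed form (via moment generating functions) to hit a
target outcome prevalence.  Two pleiotropy knobs — a direct per-allele
log-RR on the outcome and a per-allele shift of a confounder score —
model exclusion-restriction violations; the mechanism of the real-world
pleiotropic locus (an ALDH2/rs671 analogue in the default configuration)
is not documented, so both pathways are exposed rather than asserting
one.

The default `taiwan_biobank_like_config` emulates the published cohort
margins: n = 88,347; exposure (gout) prevalence 3.68% with liability
heritability 0.047 over five instruments, one pleiotropic; outcome
(hypertension) prevalence 13.52% driven by ten direct-effect SNPs; age,
sex, BMI and creatinine confounders matched to the published means and
SDs; causal effect RR 1.10 per liability SD.  Confounder effect sizes
are the package's own choices (the source reports only marginal
descriptives): modest loadings that leave `sigma_V^2 ≈ 0.89`.

What the generator does *not* emulate: linkage disequilibrium (beyond
what a user constructs by duplicating columns), population structure,
relatedness, genotyping batch effects, informative missingness, and
recall bias in questionnaire phenotypes.  A green test therefore
establishes that the estimator does what the model says under the
model's own assumptions — not that those assumptions hold in any real
cohort.

## Known limitations

- `theta2_hat` is a lower bound; reporting causal effects only at
  `theta2_hat` understates `|log RR|`, which is why the sweep is the
  primary output.
- With measured confounders that load heavily on liability, the
  `sqrt(1 - theta^2)` rescaling of the *adjusted* probit is slightly
  conservative (the adjusted residual SD is below `sqrt(1 - theta^2)`);
  with the modest confounder loadings of the bundled worlds the effect
  is well inside Monte-Carlo error, and the scale factor is isolated in
  `liability_wald_ratios` for easy amendment.
- No MR-Egger, weighted-median or outlier-robust estimators: horizontal
  pleiotropy is addressed only through the confounder screen and the
  sensitivity sweep.
- The PRS estimator refits weights per fold; with very rare exposures
  and small cohorts folds can lose a class (handled by reshuffling with
  a retry limit, then a hard error).
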