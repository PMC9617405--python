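# coarsemr

Bidirectional Mendelian randomisation (MR) with **coarsened exposures**:
causal inference between two binary disease states — think gout and
hypertension in a large population biobank — treating each binary
diagnosis as a thresholded observation of a latent continuous liability
(the Falconer model).

Standard MR needs a continuous exposure; applied to a binary one it
yields only bounds on the causal effect.  Here, a maximum-likelihood
probit regression of the disease state `D` on its genetic instruments
identifies per-allele liability effects on the residual-SD scale
(`c_j`), which the liability-scale heritability `θ²` converts to the
total-liability SD scale, `γ*_j = c_j·√(1−θ²)`.  Per-instrument Wald
ratios `b_j = β_Yj / γ*_j` (with `β_Yj` the outcome log-relative-risk
per allele from a log-linear fit) then estimate the **causal relative
risk of the outcome per 1 SD of exposure liability**, combined by
fixed/random-effects inverse-variance weighting (chosen by Cochran's Q)
and, independently, by a 10-fold cross-validated polygenic risk score
used as a single composite instrument.  Because `θ²` is only
partially identified, every estimate is swept over a grid of `θ²`
values with a data-estimated lower bound flagged.

The package is aimed at biostatisticians and genetic epidemiologists
who want the full pipeline — SNP QC (call rate, MAF, exact
Hardy–Weinberg test in controls), three-scenario logistic GWAS with LD
pruning, an instrument–confounder independence screen with FDR
adjustment, and the liability-scale estimators — as tested, scriptable
stages, plus a synthetic-cohort generator with the exact causal
structure the estimator assumes, so everything is reproducible without
access to restricted biobank data.

## Worked example

Simulate a 20,000-person cohort in which gout liability causes
hypertension (RR 1.25 per liability SD) and nothing causes gout, then
run the full bidirectional analysis:

```python
from coarsemr import (
    AnalysisConfig, CohortPhenotypes, run_bidirectional,
    bidirectional_test_config, simulate_cohort,
)

cohort = simulate_cohort(bidirectional_test_config(seed=1))
phenotypes = CohortPhenotypes(cohort.phenotypes, binary_traits=("gout", "hypertension"))
report = run_bidirectional(AnalysisConfig(seed=1), cohort.genotypes, phenotypes)
```

The same run from the shell (`python scripts/acceptance.py --seed 1
--out results/acceptance.json`) prints:

```
forward: gout -> hypertension
  instruments: ['exp_iv3', 'exp_iv2', 'exp_iv4', 'exp_iv1']
  LRT 338.68 (df=4, p=4.87e-72); theta2_hat 0.0836; Q 3.57 (p=0.311, fixed effects)
  IVW-FE: RR 1.304 [1.160, 1.466], p=8.451e-06
  PRS: RR 1.302 [1.160, 1.462], p=7.56e-06
reverse: hypertension -> gout
  instruments: ['out_iv3', 'out_iv1', 'out_iv4', 'out_iv5', 'out_iv2']
  LRT 218.81 (df=5, p=2.68e-45); theta2_hat 0.0260; Q 1.39 (p=0.845, fixed effects)
  IVW-FE: RR 1.179 [0.756, 1.839], p=0.4676
  PRS: RR 1.182 [0.750, 1.863], p=0.4701
```

Reading this: the GWAS recovered exactly the four simulated exposure
instruments; the likelihood-ratio test (LRT) shows they carry real
liability signal; Cochran's Q is homogeneous, so fixed-effects IVW is
used.  Forward, both estimators put the causal RR near the simulated
truth of 1.25 with confidence intervals excluding 1; reverse, the
intervals comfortably include 1 — the analysis finds the causal
direction that was simulated and no more.  `theta2_hat` is the
genetic-share lower bound on heritability; the persisted sweep tables
(`mr_sweep_*.tsv`) show every estimate across the full `θ²` grid and
the 2×2 scenario cells (with/without confounder adjustment ×
before/after removal of screen-flagged SNPs).

A biobank-scale world is also bundled:
`taiwan_biobank_like_config()` simulates 88,347 individuals with gout
prevalence 3.68% (five instruments, `θ² = 0.047`, one pleiotropic
rs671-analogue that the confounder screen flags and removes) and
hypertension prevalence 13.52% (ten instruments).

## Command line

Each stage reads/writes plain text (PLINK `.raw`-style genotypes, CSV
phenotypes, TSV tables, JSON summaries):

```bash
coarsemr simulate --seed 2022 --out-genotypes g.raw --out-phenotypes p.csv
coarsemr qc    --genotypes g.raw --phenotypes p.csv --exposure gout --out qc.tsv
coarsemr gwas  --genotypes g.raw --phenotypes p.csv --exposure gout --out assoc.tsv
coarsemr screen --genotypes g.raw --phenotypes p.csv --instruments rs1,rs2 --out screen.tsv
coarsemr mr    --genotypes g.raw --phenotypes p.csv --exposure gout --outcome hypertension \
               --instruments rs1,rs2 --theta2 0.04 --theta2 0.07 --out sweep.tsv
coarsemr run   --config analysis.yaml --out results/
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` recomputes the
package's headline analysis from scratch — simulating the bundled
forward-only causal cohort from the seed and running the complete
bidirectional pipeline on it — prints the per-direction summaries shown
above, and writes the results JSON to `--out`.

## Layout

- `src/coarsemr/simulate.py` — synthetic cohorts (liability threshold
  exposure, log-linear outcome, analytic prevalence calibration)
- `src/coarsemr/qc.py` — call rate / MAF / exact HWE filters
- `src/coarsemr/gwas.py` — logistic scans, LD pruning, instrument selection
- `src/coarsemr/screen.py` — instrument–confounder independence, BH-FDR
- `src/coarsemr/mr.py` — probit genetic share, LRT, `θ²` bound, Wald
  ratios, Cochran's Q, IVW, PRS, sensitivity sweep
- `src/coarsemr/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, files
- `docs/methods.md` — model, assumptions, defaults, limitations
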