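"""SNP quality control: call rate, Hardy-Weinberg equilibrium, MAF.

The HWE test is the exact conditional test: given the observed allele
counts, every attainable heterozygote count has a hypergeometric-type
probability under random mating, and the two-sided p-value sums the
probabilities of all configurations no more likely than the observed one.
A chi-square variant (1 df, no continuity correction) is available behind
a switch.

Filters mirror standard array QC: SNPs are removed when the genotype
missing rate exceeds ``max_missing_rate``, when MAF falls below
``maf_min``, or when the HWE p-value *in controls* falls below
``hwe_p_min``.  Call rate and MAF use all individuals; HWE uses controls
only, since true associations distort genotype frequencies in cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import ConfigError, DataError, GenotypeMatrix

__all__ = ["QcThresholds", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QcThresholds:
    """SNP-level QC thresholds (all proportions/probabilities in [0, 1])."""

    max_missing_rate: float = 0.1
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"QC threshold {name}={v} outside [0, 1]")


def _hwe_het_log_probs(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every attainable heterozygote count.

    Conditional on allele counts ``n_a`` (reference) and ``n_b``
    (alternate), heterozygote counts share the parity of min(n_a, n_b)
    and run from that parity up to min(n_a, n_b).
    """
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    # log P(het = h | n_a, n_b) up to a shared constant:
    #   2^h * n! / (homA! * h! * homB!)  with n = (n_a + n_b) / 2
    logp = hets * np.log(2.0) - gammaln(hom_a + 1) - gammaln(hets + 1) - gammaln(hom_b + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact"
) -> float:
    """Two-sided Hardy-Weinberg equilibrium test from genotype counts.

    Parameters
    ----------
    n_hom_ref, n_het, n_hom_alt
        Counts of the three genotype classes (non-negative, total > 0).
    method
        ``"exact"`` (default): conditional exact test summing the
        probabilities of all heterozygote configurations at most as
        probable as the observed one.  ``"chi2"``: 1-df goodness-of-fit
        chi-square against expected frequencies p^2, 2pq, q^2.

    Returns
    -------
    float
        p-value in (0, 1]; symmetric in swapping the homozygote classes.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise DataError(f"genotype counts must be non-negative integers: {counts}")
    n = sum(counts)
    if n == 0:
        raise DataError("all genotype counts are zero: HWE test undefined")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: single attainable configuration
    if method == "chi2":
        p_ref = n_a / (2.0 * n)
        expected = n * np.array([p_ref**2, 2 * p_ref * (1 - p_ref), (1 - p_ref) ** 2])
        stat = np.sum((np.array(counts, float) - expected) ** 2 / expected)
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ConfigError(f"unknown HWE method {method!r}")
    hets, probs = _hwe_het_log_probs(n_a, n_b)
    p_obs = probs[hets == n_het][0]
    # small relative slack keeps ties (e.g. the observed configuration
    # itself) inside the sum despite floating-point rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds,
    control_mask: np.ndarray,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs by call rate, MAF and HWE-in-controls.

    Returns the matrix restricted to kept SNPs together with a per-SNP
    report (``call_rate``, ``maf``, ``hwe_p``, ``kept``,
    ``removal_reason``).  ``removal_reason`` records the first violated
    filter in the order call_rate -> maf -> hwe; the kept set does not
    depend on that order.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.shape[0] != genotypes.n_samples:
        raise DataError(
            f"control mask length {control_mask.shape[0]} != "
            f"number of individuals {genotypes.n_samples}"
        )
    if control_mask.sum() == 0:
        raise DataError("empty control set: HWE-in-controls undefined")

    call_rate = genotypes.call_rate()
    maf = genotypes.maf()
    counts = genotypes.genotype_counts(sample_mask=control_mask)

    hwe_p = {}
    for snp, row in counts.iterrows():
        total = int(row.sum())
        if total == 0:
            hwe_p[snp] = np.nan
            continue
        hwe_p[snp] = hwe_exact_test(
            int(row.n_hom_ref), int(row.n_het), int(row.n_hom_alt), method=hwe_method
        )
    hwe_p = pd.Series(hwe_p, name="hwe_p")

    report = pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p.reindex(genotypes.snp_ids)}
    )
    report.index.name = "snp"

    reasons = []
    for snp in genotypes.snp_ids:
        r = report.loc[snp]
        if (1.0 - r.call_rate) > thresholds.max_missing_rate:
            reasons.append("call_rate")
        elif not (r.maf >= thresholds.maf_min):  # NaN maf (no calls) also fails
            reasons.append("maf")
        elif not (r.hwe_p >= thresholds.hwe_p_min):
            reasons.append("hwe")
        else:
            reasons.append("")
    report["kept"] = [r == "" for r in reasons]
    report["removal_reason"] = reasons

    kept_ids = report.index[report["kept"]].tolist()
    return genotypes.subset_snps(kept_ids), report
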