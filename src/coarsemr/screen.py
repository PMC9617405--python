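"""Instrument-confounder independence screen.

Valid instruments must be independent of measured confounders (the
exogeneity condition restricted to what is measured).  Each instrument is
tested against each confounder — chi-square test of independence on the
3-level genotype for categorical confounders, Spearman rank correlation of
allele count against value for continuous ones — with Benjamini-Hochberg
FDR adjustment across all (SNP, confounder) pairs jointly.  Instruments
failing the screen are removed and the MR re-run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import ConfigError, DataError, GenotypeMatrix
from .gwas import InstrumentSet

__all__ = ["bh_adjust", "confounder_independence", "filter_instruments"]

_VALID_TYPES = {"categorical", "continuous"}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def confounder_independence(
    genotypes: GenotypeMatrix,
    instruments: InstrumentSet,
    confounders: pd.DataFrame,
    confounder_types: dict[str, str],
) -> pd.DataFrame:
    """Test each instrument against each measured confounder.

    Returns a table with one row per testable (SNP, confounder) pair:
    ``snp, confounder, test, statistic, p_raw, p_adj`` where ``p_adj`` is
    the BH-FDR adjusted p-value computed jointly over all pairs.
    Genotype columns with fewer than two observed levels are skipped with
    a warning.
    """
    bad = {c: t for c, t in confounder_types.items() if t not in _VALID_TYPES}
    if bad:
        raise ConfigError(f"confounder types must be in {_VALID_TYPES}: {bad}")
    missing = [c for c in confounder_types if c not in confounders.columns]
    if missing:
        raise DataError(f"confounders absent from table: {missing}")

    rows = []
    for snp in instruments.snps:
        g_all = genotypes.dosages[snp].to_numpy()
        for conf, ctype in confounder_types.items():
            v_all = confounders[conf].to_numpy(dtype=float)
            mask = ~np.isnan(g_all) & ~np.isnan(v_all)
            g, v = g_all[mask], v_all[mask]
            if len(np.unique(g)) < 2:
                warnings.warn(
                    f"SNP {snp!r} has < 2 observed genotype levels: "
                    f"test against {conf!r} skipped"
                )
                continue
            if ctype == "categorical":
                tab = pd.crosstab(g, v)
                stat, p, _, _ = chi2_contingency(tab.to_numpy())
                test = "chi-square"
            else:
                stat, p = spearmanr(g, v)
                test = "spearman"
            rows.append((snp, conf, test, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["snp", "confounder", "test", "statistic", "p_raw"])
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def filter_instruments(
    instruments: InstrumentSet,
    tests: pd.DataFrame,
    alpha: float,
    use_adjusted: bool = True,
) -> InstrumentSet:
    """Drop instruments associated with any measured confounder.

    A SNP is removed when its (FDR-adjusted by default) p-value against
    *any* confounder is strictly below ``alpha``.  The returned set
    records the screen outcome in provenance; removals are reported via
    the set's warning list.  An empty result is allowed (with a warning).
    """
    untested = set(instruments.snps) - set(tests["snp"]) if len(instruments.snps) else set()
    if untested:
        raise DataError(f"screen table does not cover instruments: {sorted(untested)}")
    col = "p_adj" if use_adjusted else "p_raw"
    flagged = tests.loc[tests[col] < alpha, "snp"].unique().tolist()
    removed = [s for s in instruments.snps if s in flagged]
    out = instruments.without(removed)
    if removed:
        out.warnings.append(
            f"confounder screen removed {len(removed)} instrument(s) at "
            f"{col} < {alpha}: {removed}"
        )
    if not out.snps:
        warnings.warn("confounder screen removed every instrument")
    return out
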