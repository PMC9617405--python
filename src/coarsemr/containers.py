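"""Shared data containers: genotype matrices and phenotype tables.

Genotypes are additive allele counts (dosages) in {0, 1, 2}, stored as
float64 with NaN marking missing calls, one column per SNP, one row per
individual.  SNP metadata (chromosome, position, alleles) travels with the
matrix so that downstream stages can rank and report by locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "CohortPhenotypes", "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid analysis or simulation configuration."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def default_snp_meta(snp_ids) -> pd.DataFrame:
    """Placeholder metadata for matrices built in memory (tests, simulation)."""
    n = len(snp_ids)
    return pd.DataFrame(
        {
            "chromosome": ["1"] * n,
            "position": np.arange(1, n + 1, dtype=int),
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
        },
        index=pd.Index(snp_ids, name="snp"),
    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive allele counts with per-SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame of allele counts; index = sample ids, columns = SNP ids.
        Entries must be 0, 1, 2 or NaN (missing call).
    snp_meta
        DataFrame indexed by SNP id with columns ``chromosome``,
        ``position``, ``effect_allele``, ``other_allele``.  Generated with
        placeholders when omitted.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.dosages, pd.DataFrame):
            self.dosages = pd.DataFrame(self.dosages)
        self.dosages = self.dosages.astype(float)
        if self.dosages.columns.duplicated().any():
            dup = self.dosages.columns[self.dosages.columns.duplicated()][0]
            raise DataError(f"duplicate SNP id in genotype matrix: {dup!r}")
        vals = self.dosages.to_numpy()
        ok = np.isnan(vals) | (vals == 0) | (vals == 1) | (vals == 2)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"genotype value {vals[i, j]!r} at sample "
                f"{self.dosages.index[i]!r}, SNP {self.dosages.columns[j]!r} "
                "is not in {0, 1, 2, NA}"
            )
        if self.snp_meta is None:
            self.snp_meta = default_snp_meta(list(self.dosages.columns))
        else:
            missing = set(self.dosages.columns) - set(self.snp_meta.index)
            if missing:
                raise DataError(f"snp_meta lacks rows for SNPs: {sorted(missing)}")
            self.snp_meta = self.snp_meta.loc[list(self.dosages.columns)]

    # ---- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    # ---- summaries -------------------------------------------------------
    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per SNP."""
        return self.dosages.notna().mean(axis=0)

    def effect_allele_freq(self) -> pd.Series:
        """Frequency of the effect (counted) allele among non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        """Minor allele frequency: the effect-allele frequency folded at 0.5."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self, sample_mask: np.ndarray | None = None) -> pd.DataFrame:
        """Counts of genotypes 0/1/2 per SNP, optionally within a sample subset."""
        d = self.dosages if sample_mask is None else self.dosages.loc[np.asarray(sample_mask)]
        vals = d.to_numpy()
        out = {g: np.nansum(vals == g, axis=0).astype(int) for g in (0, 1, 2)}
        return pd.DataFrame(
            {"n_hom_ref": out[0], "n_het": out[1], "n_hom_alt": out[2]},
            index=pd.Index(self.snp_ids, name="snp"),
        )

    # ---- subsetting ------------------------------------------------------
    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        unknown = set(snp_ids) - set(self.dosages.columns)
        if unknown:
            raise DataError(f"unknown SNP ids: {sorted(unknown)}")
        return GenotypeMatrix(self.dosages[snp_ids].copy(), self.snp_meta.loc[snp_ids].copy())

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)].copy(), self.snp_meta.copy())


@dataclass
class CohortPhenotypes:
    """Per-individual phenotype/covariate table.

    ``table`` is indexed by sample id and holds binary disease columns
    (0/1) plus covariates.  ``binary_traits`` names columns that must be
    dichotomous.
    """

    table: pd.DataFrame
    binary_traits: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for trait in self.binary_traits:
            if trait not in self.table.columns:
                raise DataError(f"binary trait {trait!r} not in phenotype table")
            vals = self.table[trait].dropna().unique()
            if not set(vals) <= {0, 1}:
                raise DataError(f"trait {trait!r} is not coded 0/1: {sorted(vals)[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def trait(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()
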