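"""File I/O: PLINK .raw-style genotype text, phenotype CSV, config YAML/JSON."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CohortPhenotypes, DataError, GenotypeMatrix, default_snp_meta
from .simulate import SyntheticCohort

logger = logging.getLogger(__name__)

RAW_FIXED_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotypes_raw(genotypes: GenotypeMatrix, path, sex: np.ndarray | None = None) -> None:
    """Write a PLINK .raw-style whitespace-delimited genotype file.

    Header: FID IID PAT MAT SEX PHENOTYPE then one ``<snp>_<allele>``
    column per SNP; missing calls as NA.  SEX uses PLINK coding
    (1 = male, 2 = female, 0 = unknown); PHENOTYPE is written as -9.
    """
    n = genotypes.n_samples
    out = pd.DataFrame(
        {
            "FID": genotypes.sample_ids,
            "IID": genotypes.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": sex if sex is not None else np.zeros(n, dtype=int),
            "PHENOTYPE": -9,
        }
    )
    for snp in genotypes.snp_ids:
        allele = genotypes.snp_meta.loc[snp, "effect_allele"]
        vals = genotypes.dosages[snp].to_numpy()
        out[f"{snp}_{allele}"] = ["NA" if np.isnan(v) else str(int(v)) for v in vals]
    out.to_csv(path, sep=" ", index=False)


def read_genotypes_raw(path) -> GenotypeMatrix:
    """Parse a PLINK .raw-style file into a :class:`GenotypeMatrix`.

    Any genotype token outside {0, 1, 2, NA} raises :class:`DataError`
    naming the row and column.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:
        raise DataError(f"cannot parse genotype file {path}: {exc}") from exc
    missing_fixed = [c for c in RAW_FIXED_COLS if c not in df.columns]
    if missing_fixed:
        raise DataError(
            f"malformed .raw header in {path} (line 1): missing columns {missing_fixed}"
        )
    snp_cols = [c for c in df.columns if c not in RAW_FIXED_COLS]
    dosages = {}
    meta_rows = {}
    for col in snp_cols:
        snp, _, allele = col.rpartition("_")
        if not snp:
            snp, allele = col, "A"
        tokens = df[col].astype(str)
        ok = tokens.isin(["0", "1", "2", "NA", "nan"])
        if not ok.all():
            i = int(np.argmax(~ok.to_numpy()))
            raise DataError(
                f"invalid genotype token {tokens.iloc[i]!r} at data row {i + 1}, "
                f"column {col!r} of {path}"
            )
        dosages[snp] = tokens.map({"0": 0.0, "1": 1.0, "2": 2.0}).astype(float)
        meta_rows[snp] = allele
    mat = pd.DataFrame(dosages)
    mat.index = df["IID"].tolist()
    meta = default_snp_meta(list(mat.columns))
    meta["effect_allele"] = [meta_rows[s] for s in mat.columns]
    return GenotypeMatrix(mat, meta)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=True, index_label="IID", float_format="%.10g")


def read_phenotypes_csv(path, binary_traits: tuple[str, ...] = ()) -> CohortPhenotypes:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse phenotype file {path}: {exc}") from exc
    if "IID" not in df.columns:
        raise DataError(f"phenotype file {path} lacks an IID column")
    df["IID"] = df["IID"].astype(str)
    return CohortPhenotypes(df.set_index("IID"), binary_traits=binary_traits)


def write_cohort(cohort: SyntheticCohort, genotype_path, phenotype_path, config_path=None) -> None:
    """Persist a simulated cohort as .raw genotypes + CSV phenotypes (+ config)."""
    sex = None
    if "sex" in cohort.phenotypes.columns:
        # PLINK coding: 1 = male, 2 = female
        sex = np.where(cohort.phenotypes["sex"].to_numpy() == 1, 1, 2)
    write_genotypes_raw(cohort.genotypes, genotype_path, sex=sex)
    write_phenotypes_csv(cohort.phenotypes, phenotype_path)
    if config_path is not None:
        dump_config(cohort.true_parameters["config"], config_path)


def load_cohort(
    genotype_path, phenotype_path, binary_traits: tuple[str, ...] = ()
) -> tuple[GenotypeMatrix, CohortPhenotypes]:
    """Load and align genotypes with phenotypes on sample id (inner join).

    Individuals present in only one file are dropped with a logged count;
    a mismatch above 50% aborts (the files almost surely describe
    different cohorts).
    """
    genotypes = read_genotypes_raw(genotype_path)
    phenotypes = read_phenotypes_csv(phenotype_path, binary_traits=binary_traits)
    g_ids = [str(s) for s in genotypes.sample_ids]
    genotypes.dosages.index = g_ids
    p_ids = [str(s) for s in phenotypes.sample_ids]
    common = [s for s in g_ids if s in set(p_ids)]
    n_union = len(set(g_ids) | set(p_ids))
    if n_union == 0 or len(common) / n_union < 0.5:
        raise DataError(
            f"sample id mismatch: only {len(common)} of {n_union} ids shared "
            f"between {genotype_path} and {phenotype_path}"
        )
    dropped_g = len(g_ids) - len(common)
    dropped_p = len(p_ids) - len(common)
    if dropped_g or dropped_p:
        logger.info(
            "load_cohort: dropped %d genotype-only and %d phenotype-only individuals",
            dropped_g,
            dropped_p,
        )
    gm = genotypes.subset_samples(common)
    ph = CohortPhenotypes(phenotypes.table.loc[common].copy(), binary_traits=binary_traits)
    return gm, ph


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------
def dump_config(config: dict, path) -> None:
    path = Path(path)
    payload = json.loads(json.dumps(config, default=float))
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_config_file(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
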