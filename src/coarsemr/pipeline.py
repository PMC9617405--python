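"""End-to-end bidirectional analysis: QC -> GWAS -> screen -> liability MR.

Each direction (exposure -> outcome and the reverse) runs SNP QC, the
three-scenario logistic GWAS, significance intersection with LD pruning,
the instrument-confounder screen, and then the liability-scale MR in a
2 x 2 grid of scenario cells: with/without measured confounders crossed
with before/after removal of screen-flagged SNPs.  Every cell reports the
instrument-strength LRT, the estimated theta^2 lower bound, Cochran's Q
and the IVW + PRS sensitivity sweep over the direction's theta^2 grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as cio
from .containers import CohortPhenotypes, ConfigError, DataError, GenotypeMatrix
from .gwas import InstrumentSet, logistic_scan, select_instruments
from .mr import SweepResult, sensitivity_sweep
from .qc import QcThresholds, apply_qc
from .screen import confounder_independence, filter_instruments

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "DirectionReport", "RunReport", "run_direction", "run_bidirectional"]


class AnalysisConfig(BaseModel):
    """Configuration of a full bidirectional run (paths may be None when
    the cohort is passed in memory)."""

    genotype_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    exposure: str = "gout"
    outcome: str = "hypertension"
    confounders: dict[str, str] = Field(
        default_factory=lambda: {
            "age": "continuous",
            "sex": "categorical",
            "bmi": "continuous",
            "creatinine": "continuous",
        }
    )
    gwas_scenarios: list[list[str]] = Field(
        default_factory=lambda: [[], ["age", "sex"], ["age", "sex", "bmi"]]
    )
    max_missing_rate: float = 0.1
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    gwas_p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    theta2_grid_forward: list[float] = Field(default_factory=lambda: [0.04, 0.07, 0.14])
    theta2_grid_reverse: list[float] = Field(default_factory=lambda: [0.01, 0.07, 0.14, 0.21])
    screen_alpha: float = 0.05
    screen_use_adjusted_p: bool = True
    prs_folds: int = 10
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.exposure == self.outcome:
            raise ValueError("exposure and outcome must differ")
        for grid in (self.theta2_grid_forward, self.theta2_grid_reverse):
            if any(not 0.0 <= t < 1.0 for t in grid):
                raise ValueError(f"theta2 grid outside [0, 1): {grid}")
        if not 0.0 < self.gwas_p_threshold < 1.0:
            raise ValueError("gwas_p_threshold outside (0, 1)")
        for scen in self.gwas_scenarios:
            for c in scen:
                if c not in self.confounders:
                    raise ValueError(f"GWAS scenario covariate {c!r} not among confounders")
        return self

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            max_missing_rate=self.max_missing_rate,
            hwe_p_min=self.hwe_p_min,
            maf_min=self.maf_min,
        )

    def config_hash(self) -> str:
        # output_dir is presentation, not analysis: two runs of the same
        # analysis written to different places must hash identically
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class DirectionReport:
    """All artefacts of one causal direction."""

    def __init__(self, exposure: str, outcome: str):
        self.exposure = exposure
        self.outcome = outcome
        self.estimable = True
        self.note = ""
        self.qc_report: pd.DataFrame | None = None
        self.association_tables: list[pd.DataFrame] = []
        self.instruments: InstrumentSet | None = None
        self.screen_table: pd.DataFrame | None = None
        self.screened_instruments: InstrumentSet | None = None
        # keys: (remove_snps: bool, adjust_confounders: bool)
        self.cells: dict[tuple[bool, bool], SweepResult] = {}

    def summary(self) -> dict:
        out = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "estimable": self.estimable,
            "note": self.note,
            "n_instruments": len(self.instruments) if self.instruments else 0,
            "instruments": self.instruments.snps if self.instruments else [],
            "removed_by_screen": (
                [s for s in self.instruments.snps if s not in self.screened_instruments.snps]
                if self.instruments and self.screened_instruments
                else []
            ),
            "cells": {},
        }
        for (remove, adjust), sweep in self.cells.items():
            key = f"remove={remove}|confounders={adjust}"
            at_hat = sweep.table[sweep.table["is_estimated"]]
            out["cells"][key] = {
                "lrt_stat": sweep.lrt[0],
                "lrt_df": sweep.lrt[1],
                "lrt_p": sweep.lrt[2],
                "theta2_hat": sweep.theta2_hat,
                "Q": sweep.heterogeneity.Q if sweep.heterogeneity else None,
                "Q_p": sweep.heterogeneity.p if sweep.heterogeneity else None,
                "model": at_hat["model"].iloc[0] if len(at_hat) else None,
                "estimates_at_theta2_hat": at_hat[
                    ["method", "rr", "ci_low", "ci_high", "p"]
                ].to_dict("records"),
            }
        return out


class RunReport:
    """Bidirectional results plus provenance."""

    def __init__(self, config: AnalysisConfig):
        self.config = config
        self.directions: dict[str, DirectionReport] = {}

    def summary(self) -> dict:
        from . import __version__

        return {
            "package": "coarsemr",
            "version": __version__,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "directions": {k: d.summary() for k, d in self.directions.items()},
        }


def run_direction(
    genotypes: GenotypeMatrix,
    phenotypes: CohortPhenotypes,
    exposure: str,
    outcome: str,
    config: AnalysisConfig,
    theta2_grid: list[float],
) -> DirectionReport:
    """One causal direction: QC through the theta^2 sensitivity sweep."""
    report = DirectionReport(exposure, outcome)
    D_all = phenotypes.trait(exposure)
    Y_all = phenotypes.trait(outcome)
    conf_names = list(config.confounders)
    conf_table = phenotypes.table[conf_names] if conf_names else None

    controls = D_all == 0
    qc_geno, qc_rep = apply_qc(genotypes, config.qc_thresholds(), controls)
    report.qc_report = qc_rep
    logger.info(
        "[%s->%s] QC: %d of %d SNPs kept", exposure, outcome, qc_geno.n_snps, genotypes.n_snps
    )

    tables = logistic_scan(
        qc_geno, D_all, conf_table, config.gwas_scenarios
    )
    report.association_tables = tables
    instruments = select_instruments(
        tables, config.gwas_p_threshold, qc_geno, config.r2_threshold
    )
    report.instruments = instruments
    logger.info(
        "[%s->%s] GWAS: %d instrument(s) after intersection + pruning",
        exposure, outcome, len(instruments),
    )
    if not instruments.snps:
        report.estimable = False
        report.note = "no instruments passed GWAS selection: direction not estimable"
        logger.warning("[%s->%s] %s", exposure, outcome, report.note)
        return report

    screen = confounder_independence(qc_geno, instruments, phenotypes.table, config.confounders)
    report.screen_table = screen
    screened = filter_instruments(
        instruments, screen, config.screen_alpha, use_adjusted=config.screen_use_adjusted_p
    )
    report.screened_instruments = screened
    logger.info(
        "[%s->%s] screen: %d of %d instrument(s) retained",
        exposure, outcome, len(screened), len(instruments),
    )

    for remove_snps, inst in ((False, instruments), (True, screened)):
        if not inst.snps:
            report.note = "confounder screen removed all instruments in the remove-SNPs cells"
            continue
        Z = genotypes.dosages[inst.snps]
        for adjust in (False, True):
            M = conf_table if adjust and conf_table is not None else None
            sweep = sensitivity_sweep(
                D_all, Y_all, Z, M, theta2_grid,
                n_folds=config.prs_folds, seed=config.seed,
            )
            report.cells[(remove_snps, adjust)] = sweep
    return report


def run_bidirectional(
    config: AnalysisConfig,
    genotypes: GenotypeMatrix | None = None,
    phenotypes: CohortPhenotypes | None = None,
) -> RunReport:
    """Full bidirectional analysis; loads the cohort from files if not given.

    A direction whose instrument search comes up empty is reported as not
    estimable and the run continues.  Identical config + seed + inputs
    give identical reports (all randomness flows from ``config.seed``).
    """
    if genotypes is None or phenotypes is None:
        if config.genotype_path is None or config.phenotype_path is None:
            raise ConfigError("no cohort in memory and no genotype/phenotype paths configured")
        genotypes, phenotypes = cio.load_cohort(
            config.genotype_path,
            config.phenotype_path,
            binary_traits=(config.exposure, config.outcome),
        )
    for trait in (config.exposure, config.outcome):
        if trait not in phenotypes.table.columns:
            raise DataError(f"trait {trait!r} missing from phenotype table")
    for conf in config.confounders:
        if conf not in phenotypes.table.columns:
            raise DataError(f"confounder {conf!r} missing from phenotype table")

    report = RunReport(config)
    report.directions["forward"] = run_direction(
        genotypes, phenotypes, config.exposure, config.outcome, config,
        config.theta2_grid_forward,
    )
    report.directions["reverse"] = run_direction(
        genotypes, phenotypes, config.outcome, config.exposure, config,
        config.theta2_grid_reverse,
    )
    if config.output_dir:
        persist_report(report, Path(config.output_dir))
    return report


def persist_report(report: RunReport, outdir: Path) -> None:
    """Write every intermediate table (TSV) and the JSON run summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    for name, d in report.directions.items():
        prefix = outdir / name
        prefix.mkdir(exist_ok=True)
        if d.qc_report is not None:
            d.qc_report.to_csv(prefix / "qc_report.tsv", sep="\t", float_format="%.10g")
        if d.association_tables:
            pd.concat(d.association_tables).to_csv(
                prefix / "associations.tsv", sep="\t", index=False, float_format="%.10g"
            )
        if d.screen_table is not None:
            d.screen_table.to_csv(
                prefix / "confounder_screen.tsv", sep="\t", index=False, float_format="%.10g"
            )
        for (remove, adjust), sweep in d.cells.items():
            tag = f"remove{int(remove)}_conf{int(adjust)}"
            sweep.table.to_csv(
                prefix / f"mr_sweep_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
            )
    (outdir / "summary.json").write_text(json.dumps(report.summary(), indent=2, default=float))
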