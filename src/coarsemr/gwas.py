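"""Instrument selection: logistic association scans, LD pruning, intersection.

Candidate instruments are SNPs reaching genome-wide significance
(default p < 5e-8) for the exposure in *every* covariate-adjustment
scenario (unadjusted; age + sex; age + sex + BMI by convention), then
greedily LD-pruned so no two surviving SNPs have squared dosage
correlation at or above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .containers import ConfigError, DataError, GenotypeMatrix

__all__ = ["InstrumentSet", "logistic_scan", "ld_prune", "select_instruments", "pairwise_r2"]


@dataclass
class InstrumentSet:
    """Ordered instruments with exposure associations and provenance flags."""

    snps: list[str]
    stats: pd.DataFrame  # indexed by snp: beta, se, p, n (ranking scenario)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.snps)) != len(self.snps):
            raise DataError("duplicate SNP ids in instrument set")
        if self.provenance.empty and self.snps:
            self.provenance = pd.DataFrame(
                {
                    "passed_gwas": True,
                    "passed_pruning": True,
                    "passed_confounder_screen": pd.NA,
                    "pleiotropy_suspect": False,
                },
                index=pd.Index(self.snps, name="snp"),
            )

    def __len__(self) -> int:
        return len(self.snps)

    def without(self, removed: list[str], reason_flag: str = "passed_confounder_screen") -> "InstrumentSet":
        """New set with ``removed`` dropped and the provenance flag updated."""
        prov = self.provenance.copy()
        for snp in self.snps:
            if reason_flag in prov.columns:
                prov.loc[snp, reason_flag] = snp not in removed
        kept = [s for s in self.snps if s not in removed]
        return InstrumentSet(
            snps=kept,
            stats=self.stats.loc[kept].copy() if not self.stats.empty else self.stats,
            provenance=prov,
            warnings=list(self.warnings),
        )


def _logit_nll(beta: np.ndarray, y: np.ndarray, X: np.ndarray, ridge: float) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) - y*eta, numerically stable
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    pen = 0.5 * ridge * np.sum(beta[1:] ** 2)  # never penalise the intercept
    return -(ll) + pen


def _logit_grad(beta: np.ndarray, y: np.ndarray, X: np.ndarray, ridge: float) -> np.ndarray:
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    g = -X.T @ (y - mu)
    g[1:] += ridge * beta[1:]
    return g


def _fit_logit_single(y: np.ndarray, X: np.ndarray, ridge: float = 1e-4):
    """ML logistic fit; ridge-penalised quasi-Newton retry on failure.

    Returns (params, bse, converged).  The ridge retry targets perfect
    separation at low MAF, where plain Newton diverges.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.bse)):
            return np.asarray(res.params), np.asarray(res.bse), True
    except Exception:
        pass
    start = np.zeros(X.shape[1])
    opt = minimize(
        _logit_nll, start, args=(y, X, ridge), jac=_logit_grad, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    mu = 1.0 / (1.0 + np.exp(-(X @ opt.x)))
    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    info[1:, 1:] += ridge * np.eye(X.shape[1] - 1)
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return opt.x, np.full(X.shape[1], np.nan), False
    return opt.x, bse, bool(opt.success)


def logistic_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    covariate_scenarios: list[list[str]],
    scenario_labels: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Per-SNP logistic association scan under several covariate scenarios.

    Each scenario fits, per SNP, a maximum-likelihood logistic regression
    of the binary phenotype on allele count plus the scenario's
    covariates (complete cases per SNP).  Non-converged SNPs are flagged
    via the ``converged`` column, never dropped.

    Returns one table per scenario with columns
    ``snp, scenario, beta, se, p, n, converged``.
    """
    y_all = np.asarray(phenotype, dtype=float)
    classes = np.unique(y_all[~np.isnan(y_all)])
    if len(classes) < 2:
        raise DataError("phenotype is constant: logistic scan undefined")
    if not set(classes) <= {0.0, 1.0}:
        raise DataError(f"phenotype must be binary 0/1, got values {classes[:5]}")
    if scenario_labels is None:
        scenario_labels = [
            "unadjusted" if not cols else "adj_" + "_".join(cols)
            for cols in covariate_scenarios
        ]
    tables = []
    from scipy.stats import norm

    for label, cols in zip(scenario_labels, covariate_scenarios):
        if cols and covariates is None:
            raise ConfigError(f"scenario {label!r} needs covariates {cols} but none supplied")
        missing_cols = [c for c in cols if covariates is None or c not in covariates.columns]
        if missing_cols:
            raise ConfigError(f"covariates not available: {missing_cols}")
        C = covariates[cols].to_numpy(dtype=float) if cols else None
        rows = []
        for snp in genotypes.snp_ids:
            g = genotypes.dosages[snp].to_numpy()
            mask = ~np.isnan(g) & ~np.isnan(y_all)
            if C is not None:
                mask &= ~np.isnan(C).any(axis=1)
            y = y_all[mask]
            parts = [np.ones(mask.sum()), g[mask]]
            if C is not None:
                parts.extend(C[mask].T)
            X = np.column_stack(parts)
            if len(np.unique(y)) < 2 or np.nanstd(g[mask]) == 0:
                rows.append((snp, label, np.nan, np.nan, np.nan, int(mask.sum()), False))
                continue
            params, bse, converged = _fit_logit_single(y, X)
            beta, se = params[1], bse[1]
            p = 2 * norm.sf(abs(beta / se)) if np.isfinite(se) and se > 0 else np.nan
            if p == 0.0:
                p = np.nextafter(0, 1)  # keep p in (0, 1]
            rows.append((snp, label, beta, se, p, int(mask.sum()), converged))
        tables.append(
            pd.DataFrame(rows, columns=["snp", "scenario", "beta", "se", "p", "n", "converged"])
        )
    return tables


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    mask = ~np.isnan(x) & ~np.isnan(y)
    xm, ym = x[mask], y[mask]
    if xm.std() == 0 or ym.std() == 0:
        return np.nan
    r = np.corrcoef(xm, ym)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: GenotypeMatrix, candidates: list[str], r2_threshold: float
) -> list[str]:
    """Greedy keep-best LD pruning over ranked candidates.

    Candidates are visited in the given order (callers rank by ascending
    association p); a SNP is kept iff its squared dosage correlation with
    every already-kept SNP is strictly below ``r2_threshold``.
    Monomorphic candidates (undefined r^2) are excluded with a warning.
    """
    if not 0 < r2_threshold <= 1:
        raise ConfigError(f"r2_threshold={r2_threshold} outside (0, 1]")
    unknown = set(candidates) - set(genotypes.snp_ids)
    if unknown:
        raise DataError(f"candidates absent from genotype matrix: {sorted(unknown)}")
    kept: list[str] = []
    for snp in candidates:
        g = genotypes.dosages[snp].to_numpy()
        if np.nanstd(g) == 0:
            warnings.warn(f"monomorphic candidate {snp!r} excluded from pruning (r2 undefined)")
            continue
        r2s = [pairwise_r2(g, genotypes.dosages[k].to_numpy()) for k in kept]
        if all(np.isnan(r2) or r2 < r2_threshold for r2 in r2s):
            kept.append(snp)
    return kept


def select_instruments(
    tables: list[pd.DataFrame],
    p_threshold: float,
    genotypes: GenotypeMatrix,
    r2_threshold: float,
) -> InstrumentSet:
    """Intersect per-scenario genome-wide-significant SNPs, then LD-prune.

    SNPs must pass ``p < p_threshold`` in every scenario.  A warning is
    recorded when the per-scenario significant sets differ (robust
    selections agree across adjustment scenarios).  An empty intersection
    yields an empty set with a warning, not an exception.
    """
    if not tables:
        raise ConfigError("select_instruments needs at least one association table")
    sig_sets = [set(t.loc[t["p"] < p_threshold, "snp"]) for t in tables]
    inter = set.intersection(*sig_sets)
    notes: list[str] = []
    if any(s != sig_sets[0] for s in sig_sets[1:]):
        msg = (
            "significant SNP sets differ across adjustment scenarios: "
            + "; ".join(
                f"{t['scenario'].iloc[0] if len(t) else i}: {len(s)} SNPs"
                for i, (t, s) in enumerate(zip(tables, sig_sets))
            )
        )
        warnings.warn(msg)
        notes.append(msg)
    rank_table = tables[0].set_index("snp")
    meta = genotypes.snp_meta
    ranked = sorted(
        inter,
        key=lambda s: (
            rank_table.loc[s, "p"],
            meta.loc[s, "position"] if s in meta.index else 0,
            s,
        ),
    )
    if not ranked:
        msg = "no SNP passed the GWAS threshold in all scenarios: empty instrument set"
        warnings.warn(msg)
        notes.append(msg)
        return InstrumentSet(snps=[], stats=pd.DataFrame(), warnings=notes)
    pruned = ld_prune(genotypes, ranked, r2_threshold)
    stats = rank_table.loc[pruned, ["beta", "se", "p", "n"]].copy()
    inst = InstrumentSet(snps=pruned, stats=stats, warnings=notes)
    # record pruning outcome for all intersection members
    prov = pd.DataFrame(
        {
            "passed_gwas": True,
            "passed_pruning": [s in pruned for s in ranked],
            "passed_confounder_screen": pd.NA,
            "pleiotropy_suspect": False,
        },
        index=pd.Index(ranked, name="snp"),
    )
    inst.provenance = prov
    return inst
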