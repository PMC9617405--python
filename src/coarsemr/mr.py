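"""Liability-scale Mendelian randomisation with coarsened exposures.

A binary disease state D is modelled as the thresholding of a latent
liability L with unit variance (Falconer model): D = 1{L > tau}.  The
liability splits into a genetic share G = sum_j gamma_j Z_j, a measured
confounder part and an unobserved environmental share V ~ N(0, sigma_V^2).
A maximum-likelihood probit regression of D on the instruments (plus
measured confounders M) identifies c_j = gamma_j / sigma_V — the per-allele
liability effect in residual-SD units.  With theta^2 the fraction of
liability variance that is genetic (heritability), sigma_V^2 = 1 - theta^2
when G and M are the only other sources, so

    gamma*_j = c_j * sqrt(1 - theta^2)

rescales probit coefficients to the *total* liability SD scale.  Per-SNP
Wald ratios b_j = beta_Yj / gamma*_j (outcome log-relative-risk over
liability effect) then estimate the causal log-RR of the outcome per 1 SD
of exposure liability, combined by inverse-variance weighting (fixed- or
random-effects chosen by Cochran's Q) or via a cross-validated polygenic
risk score used as a single composite instrument.

theta^2 is not estimable from the instruments alone; the genetic-share
variance of the fitted probit yields a lower bound, and the analysis is
swept over a user grid of theta^2 values as a sensitivity parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm
from sklearn.model_selection import KFold

from .containers import ConfigError, DataError
from .gwas import _fit_logit_single

__all__ = [
    "GeneticShareFit",
    "HeterogeneityResult",
    "MrEstimate",
    "SweepResult",
    "fit_genetic_share",
    "instrument_strength_lrt",
    "estimate_theta2_lower_bound",
    "outcome_scan",
    "liability_wald_ratios",
    "cochran_q",
    "ivw_combine",
    "prs_method",
    "score_associations",
    "sensitivity_sweep",
]

Z_CRIT = norm.ppf(0.975)  # 1.959964...


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class GeneticShareFit:
    """Probit fit of the coarsened exposure on its instruments (+ confounders).

    ``coef[j]`` is the liability shift per effect allele of instrument j in
    units of the residual (environmental) SD; ``s2`` is the sample variance
    of the fitted genetic share sum_j c_j Z_j on that same scale.
    """

    instruments: list[str]
    coef: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    confounder_coef: pd.Series
    llf: float
    llnull: float
    genetic_share: np.ndarray
    s2: float
    n: int
    converged: bool


@dataclass
class HeterogeneityResult:
    """Cochran's Q across per-instrument Wald ratios."""

    Q: float
    df: int
    p: float
    model: str  # "fixed" iff p >= 0.05 else "random"


@dataclass
class MrEstimate:
    """One causal estimate: log-RR of outcome per 1 SD of exposure liability."""

    method: str  # IVW-FE | IVW-RE | PRS
    theta2: float
    estimate: float
    se: float
    rr: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.rr = float(np.exp(self.estimate))
        self.ci_low = float(np.exp(self.estimate - Z_CRIT * self.se))
        self.ci_high = float(np.exp(self.estimate + Z_CRIT * self.se))
        self.p = float(2 * norm.sf(abs(self.estimate) / self.se)) if self.se > 0 else np.nan


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _as_matrix(df: pd.DataFrame | None) -> tuple[np.ndarray | None, list[str]]:
    if df is None or (hasattr(df, "empty") and df.empty):
        return None, []
    return df.to_numpy(dtype=float), list(df.columns)


def _impute_dosages(Z: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing allele counts (standard for multi-SNP scores)."""
    return Z.fillna(Z.mean(axis=0))


def _complete_rows(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= ~(np.isnan(a).any(axis=1) if a.ndim == 2 else np.isnan(a))
    return mask


# ---------------------------------------------------------------------------
# probit genetic-share fit and instrument strength
# ---------------------------------------------------------------------------
def fit_genetic_share(
    D: np.ndarray, Z: pd.DataFrame, M: pd.DataFrame | None = None
) -> GeneticShareFit:
    """ML probit of the binary exposure on instruments (+ confounders).

    Fits P(D=1 | Z, M) = Phi(sum_j c_j Z_j + eta'M - tau') together with
    the matching null model (confounders only, or intercept only) on the
    same rows.  Missing dosages are mean-imputed; rows with missing D or
    M are dropped.  Zero-variance instrument columns carry no information
    and get c_j = 0 exactly without entering the design matrix.
    """
    D = np.asarray(D, dtype=float)
    Zi = _impute_dosages(Z.astype(float))
    Mmat, mcols = _as_matrix(M)
    mask = _complete_rows(D, Mmat)
    D = D[mask]
    Zi = Zi.loc[mask]
    if Mmat is not None:
        Mmat = Mmat[mask]
    classes = np.unique(D)
    if len(classes) < 2:
        raise DataError("exposure is constant: probit fit undefined")
    if not set(classes) <= {0.0, 1.0}:
        raise DataError(f"exposure must be binary 0/1, got {classes[:5]}")

    snps = list(Z.columns)
    Zarr = Zi.to_numpy(dtype=float)
    sds = Zarr.std(axis=0)
    varying = [j for j, s in enumerate(sds) if s > 0]
    dropped = [snps[j] for j, s in enumerate(sds) if s == 0]

    n = len(D)
    parts_null = [np.ones(n)] + ([Mmat.T[i] for i in range(Mmat.shape[1])] if Mmat is not None else [])
    X_null = np.column_stack(parts_null)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_null = sm.Probit(D, X_null).fit(disp=0, maxiter=200)

    coef = pd.Series(0.0, index=snps, name="c")
    se = pd.Series(np.nan, index=snps, name="se")
    cov = pd.DataFrame(0.0, index=snps, columns=snps)
    conf_coef = pd.Series(dtype=float)

    if varying:
        Xv = Zarr[:, varying]
        X_full = np.column_stack([np.ones(n), Xv] + ([Mmat] if Mmat is not None else []))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Probit(D, X_full).fit(disp=0, maxiter=200)
            except Exception as exc:  # separation / singular design
                raise DataError(
                    f"probit fit failed for instruments {[snps[j] for j in varying]}: {exc}"
                ) from exc
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        if not (res.mle_retvals.get("converged", False) and np.all(np.isfinite(params))):
            raise DataError(
                "probit genetic-share fit did not converge; check instruments "
                f"{[snps[j] for j in varying]} for separation or collinearity"
            )
        if not np.all(np.isfinite(bse)):
            bad = [snps[varying[i]] for i in range(len(varying)) if not np.isfinite(bse[1 + i])]
            raise DataError(f"singular information for instruments {bad} (collinear?)")
        for i, j in enumerate(varying):
            coef.iloc[j] = params[1 + i]
            se.iloc[j] = bse[1 + i]
        vcv = np.asarray(res.cov_params())[1 : 1 + len(varying), 1 : 1 + len(varying)]
        for a, ja in enumerate(varying):
            for b, jb in enumerate(varying):
                cov.iloc[ja, jb] = vcv[a, b]
        if mcols:
            conf_coef = pd.Series(params[1 + len(varying) :], index=mcols)
        llf = float(res.llf)
    else:
        llf = float(res_null.llf)
        if mcols:
            conf_coef = pd.Series(np.asarray(res_null.params)[1:], index=mcols)

    share = Zarr @ coef.to_numpy()
    s2 = float(np.var(share, ddof=1)) if n > 1 else 0.0
    if dropped:
        warnings.warn(f"zero-variance instruments carry no information: {dropped}")
    return GeneticShareFit(
        instruments=snps,
        coef=coef,
        se=se,
        cov=cov,
        confounder_coef=conf_coef,
        llf=llf,
        llnull=float(res_null.llf),
        genetic_share=share,
        s2=s2,
        n=n,
        converged=True,
    )


def instrument_strength_lrt(fit: GeneticShareFit, k: int | None = None) -> tuple[float, int, float]:
    """Likelihood-ratio test that all instrument coefficients are zero.

    Returns (statistic, df, p) with statistic = 2(ll_full - ll_null)
    clipped at zero and df = number of instruments.  Large values support
    (but cannot prove) that the genetic share is made of relevant
    instruments.
    """
    if k is None:
        k = len(fit.instruments)
    stat = max(0.0, 2.0 * (fit.llf - fit.llnull))
    p = float(chi2.sf(stat, df=k)) if k > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, k, p


def estimate_theta2_lower_bound(fit: GeneticShareFit) -> float:
    """Heritability lower bound from the fitted genetic share.

    On the residual scale (V normalised to unit variance) the fitted share
    has variance s^2, so total liability variance is at least s^2 + 1 and
    the genetic fraction at least s^2 / (s^2 + 1).  Equality holds when
    the instruments span the whole genetic share; unmeasured variants make
    this a lower bound.
    """
    return float(fit.s2 / (fit.s2 + 1.0))


# ---------------------------------------------------------------------------
# outcome associations (log-relative-risk scale)
# ---------------------------------------------------------------------------
def _fit_log_linear(y: np.ndarray, X: np.ndarray, family: str):
    """Log-link binary-outcome fit returning (params, robust bse, converged).

    ``poisson`` (default) uses the Poisson working likelihood with HC0
    sandwich errors — consistent for the log-RR and far more stable than
    log-binomial ML, which is attempted only when asked and falls back to
    Poisson on failure.
    """
    if family == "log-binomial":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log())).fit(
                    maxiter=200
                )
            if res.converged and np.all(np.isfinite(res.bse)):
                return np.asarray(res.params), np.asarray(res.bse), True
        except Exception:
            pass  # fall through to the Poisson working model
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0", maxiter=200)
    ok = bool(res.converged and np.all(np.isfinite(res.bse)))
    return np.asarray(res.params), np.asarray(res.bse), ok


def outcome_scan(
    Y: np.ndarray,
    Z: pd.DataFrame,
    M: pd.DataFrame | None = None,
    family: str = "poisson",
) -> pd.DataFrame:
    """Per-instrument log-linear association with the binary outcome.

    Fits log P(Y=1) = a + beta_Yj Z_j + delta'M separately for each
    instrument j, with robust (sandwich) standard errors.  Returns a table
    indexed by SNP with columns ``beta, se, n, converged``.
    """
    Y = np.asarray(Y, dtype=float)
    classes = np.unique(Y[~np.isnan(Y)])
    if len(classes) < 2:
        raise DataError("outcome is constant: log-linear scan undefined")
    if not set(classes) <= {0.0, 1.0}:
        raise DataError(f"outcome must be binary 0/1, got {classes[:5]}")
    Mmat, _ = _as_matrix(M)
    rows = []
    for snp in Z.columns:
        g = Z[snp].to_numpy(dtype=float)
        mask = _complete_rows(Y, g[:, None], Mmat)
        y = Y[mask]
        parts = [np.ones(mask.sum()), g[mask]]
        if Mmat is not None:
            parts.append(Mmat[mask])
        X = np.column_stack(parts)
        if np.std(g[mask]) == 0:
            rows.append((snp, np.nan, np.nan, int(mask.sum()), False))
            continue
        params, bse, ok = _fit_log_linear(y, X, family)
        rows.append((snp, float(params[1]), float(bse[1]), int(mask.sum()), ok))
    out = pd.DataFrame(rows, columns=["snp", "beta", "se", "n", "converged"]).set_index("snp")
    return out


# ---------------------------------------------------------------------------
# Wald ratios, heterogeneity, IVW
# ---------------------------------------------------------------------------
def liability_wald_ratios(
    fit: GeneticShareFit,
    outcome: pd.DataFrame,
    theta2: float,
    min_coef: float = 1e-8,
) -> pd.DataFrame:
    """Per-instrument causal ratios on the total-liability SD scale.

    gamma*_j = c_j sqrt(1 - theta2) converts residual-scale probit
    coefficients to per-total-SD liability effects; the Wald ratio is
    b_j = beta_Yj / gamma*_j with first-order (delta method) standard
    error se(beta_Yj) / |gamma*_j|.  Instruments with |c_j| below
    ``min_coef`` give unstable ratios and are excluded with a warning.
    """
    if not 0.0 <= theta2 < 1.0:
        raise ConfigError(f"theta2={theta2} outside [0, 1)")
    scale = np.sqrt(1.0 - theta2)
    rows = []
    for snp in fit.instruments:
        if snp not in outcome.index:
            raise DataError(f"no outcome association for instrument {snp!r}")
        c = float(fit.coef[snp])
        if abs(c) < min_coef:
            warnings.warn(f"instrument {snp!r} has |c| < {min_coef}: ratio unstable, excluded")
            continue
        beta_y = float(outcome.loc[snp, "beta"])
        se_y = float(outcome.loc[snp, "se"])
        gamma_star = c * scale
        rows.append((snp, beta_y, se_y, c, gamma_star, beta_y / gamma_star, se_y / abs(gamma_star)))
    return pd.DataFrame(
        rows, columns=["snp", "beta_y", "se_y", "c", "gamma_star", "wald", "wald_se"]
    ).set_index("snp")


def cochran_q(ratios: pd.DataFrame) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test over per-instrument Wald ratios.

    Q = sum_j (b_j - b_FE)^2 / se_j^2 with b_FE the fixed-effect
    (precision-weighted) mean; p from chi-square(k - 1).  Fixed effects
    are retained when p >= 0.05, else random effects.
    """
    k = len(ratios)
    if k < 2:
        raise DataError(f"Cochran's Q needs >= 2 ratios, got {k}")
    b = ratios["wald"].to_numpy()
    w = 1.0 / ratios["wald_se"].to_numpy() ** 2
    b_fe = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - b_fe) ** 2))
    p = float(chi2.sf(Q, df=k - 1))
    return HeterogeneityResult(Q=Q, df=k - 1, p=p, model="fixed" if p >= 0.05 else "random")


def ivw_combine(
    ratios: pd.DataFrame, model: str = "fixed", theta2: float = np.nan
) -> MrEstimate:
    """Inverse-variance weighted combination of Wald ratios.

    Fixed effects: precision-weighted mean with SE (sum of weights)^-1/2.
    Random effects: same point estimate, SE inflated by
    sqrt(max(1, Q / (k - 1))) (multiplicative overdispersion).  A single
    ratio forces the fixed-effect model.
    """
    k = len(ratios)
    if k == 0:
        raise DataError("cannot combine an empty ratio table")
    if model not in {"fixed", "random"}:
        raise ConfigError(f"model must be 'fixed' or 'random', got {model!r}")
    b = ratios["wald"].to_numpy()
    w = 1.0 / ratios["wald_se"].to_numpy() ** 2
    est = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if k == 1:
        model = "fixed"
    if model == "random":
        Q = float(np.sum(w * (b - est) ** 2))
        se *= float(np.sqrt(max(1.0, Q / (k - 1))))
    label = "IVW-FE" if model == "fixed" else "IVW-RE"
    return MrEstimate(method=label, theta2=theta2, estimate=est, se=se)


# ---------------------------------------------------------------------------
# PRS as a single composite instrument
# ---------------------------------------------------------------------------
def _prs_scores(
    D: np.ndarray,
    Z: pd.DataFrame,
    M: pd.DataFrame | None,
    n_folds: int,
    seed: int,
    max_retries: int = 10,
) -> np.ndarray:
    """Out-of-fold polygenic risk scores with cross-validated weights.

    Weights are logistic-regression coefficients of D on all instruments
    (+ confounders) fitted on the complementary folds, so each
    individual's score never uses their own outcome — the stand-in for an
    independent weight-training dataset.
    """
    if n_folds < 2:
        raise ConfigError(f"n_folds={n_folds} must be >= 2")
    D = np.asarray(D, dtype=float)
    Zi = _impute_dosages(Z.astype(float))
    Zarr = Zi.to_numpy(dtype=float)
    Mmat, _ = _as_matrix(M)
    n = len(D)
    for attempt in range(max_retries):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=(seed + 100_003 * attempt) % (2**31 - 1))
        splits = list(kf.split(np.arange(n)))
        if all(len(np.unique(D[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise DataError(
            f"could not build {n_folds} folds with both exposure classes "
            f"after {max_retries} reshuffles"
        )
    prs = np.empty(n)
    for train, test in splits:
        parts = [np.ones(len(train)), Zarr[train]]
        if Mmat is not None:
            parts.append(Mmat[train])
        X = np.column_stack(parts)
        params, _, _ = _fit_logit_single(D[train], X)
        w = params[1 : 1 + Zarr.shape[1]]
        prs[test] = Zarr[test] @ w
    return prs


def score_associations(
    D: np.ndarray,
    Y: np.ndarray,
    score: np.ndarray,
    M: pd.DataFrame | None = None,
    family: str = "poisson",
) -> tuple[float, float, float]:
    """Single-instrument associations for any composite score S.

    Returns (beta_YS, se_YS, c_S): the log-linear outcome association and
    the probit exposure association of the score.  The downstream causal
    ratio beta_YS / (c_S sqrt(1 - theta2)) is invariant to rescaling the
    score, since both associations scale inversely with it.
    """
    S = pd.DataFrame({"score": np.asarray(score, dtype=float)})
    fit = fit_genetic_share(D, S, M)
    c_s = float(fit.coef["score"])
    out = outcome_scan(Y, S, M, family=family)
    return float(out.loc["score", "beta"]), float(out.loc["score", "se"]), c_s


def _prs_core(
    D: np.ndarray,
    Y: np.ndarray,
    Z: pd.DataFrame,
    M: pd.DataFrame | None,
    n_folds: int,
    seed: int,
    family: str = "poisson",
) -> tuple[float, float, float]:
    """(beta_YS, se_YS, c_S) for the cross-validated PRS instrument S."""
    prs = _prs_scores(D, Z, M, n_folds, seed)
    return score_associations(D, Y, prs, M, family=family)


def prs_method(
    D: np.ndarray,
    Y: np.ndarray,
    Z: pd.DataFrame,
    M: pd.DataFrame | None,
    theta2: float,
    n_folds: int = 10,
    seed: int = 0,
    family: str = "poisson",
) -> MrEstimate:
    """Single-instrument coarsened MR using a cross-validated PRS.

    The PRS S replaces the instrument panel: probit D ~ S (+M) gives c_S,
    log-linear Y ~ S (+M) gives beta_YS, and the causal log-RR per
    liability SD is beta_YS / (c_S sqrt(1 - theta2)) with delta-method SE.
    The estimate is invariant to rescaling S (the ratio cancels scale).
    """
    if not 0.0 <= theta2 < 1.0:
        raise ConfigError(f"theta2={theta2} outside [0, 1)")
    beta_ys, se_ys, c_s = _prs_core(D, Y, Z, M, n_folds, seed, family=family)
    gamma_star = c_s * np.sqrt(1.0 - theta2)
    if abs(gamma_star) < 1e-12:
        raise DataError("PRS carries no exposure information (c_S ~ 0)")
    return MrEstimate(
        method="PRS", theta2=theta2, estimate=beta_ys / gamma_star, se=se_ys / abs(gamma_star)
    )


# ---------------------------------------------------------------------------
# sensitivity sweep over theta^2
# ---------------------------------------------------------------------------
@dataclass
class SweepResult:
    """Full per-direction MR output: fits, tests and the theta^2 sweep table."""

    fit: GeneticShareFit
    lrt: tuple[float, int, float]
    theta2_hat: float
    heterogeneity: HeterogeneityResult | None
    table: pd.DataFrame  # method, theta2, is_estimated, log_rr, se, rr, ci_low, ci_high, p, Q, Q_p, model


def sensitivity_sweep(
    D: np.ndarray,
    Y: np.ndarray,
    Z: pd.DataFrame,
    M: pd.DataFrame | None,
    theta2_grid: list[float],
    n_folds: int = 10,
    seed: int = 0,
    family: str = "poisson",
) -> SweepResult:
    """IVW and PRS estimates over a grid of theta^2 sensitivity values.

    The probit genetic-share fit, the per-instrument outcome scan and the
    cross-validated PRS fits are computed once; only the deterministic
    sqrt(1 - theta^2) rescaling varies across the grid.  The
    data-estimated lower bound theta2_hat is added to the grid and
    flagged.  Cochran's Q is invariant to theta^2 (numerator and weights
    rescale identically), so the fixed/random choice is made once.
    """
    if not theta2_grid:
        raise ConfigError("theta2 grid is empty")
    if any(not 0.0 <= t < 1.0 for t in theta2_grid):
        raise ConfigError(f"theta2 grid values outside [0, 1): {theta2_grid}")
    fit = fit_genetic_share(D, Z, M)
    lrt = instrument_strength_lrt(fit)
    theta2_hat = estimate_theta2_lower_bound(fit)
    out = outcome_scan(Y, Z, M, family=family)

    ratios0 = liability_wald_ratios(fit, out, theta2=0.0)
    if len(ratios0) >= 2:
        het = cochran_q(ratios0)
        model = het.model
    elif len(ratios0) == 1:
        het = None
        model = "fixed"
    else:
        raise DataError("no usable instrument ratios: direction not estimable")

    beta_ys, se_ys, c_s = _prs_core(D, Y, Z, M, n_folds, seed, family=family)

    grid = sorted(set(float(t) for t in theta2_grid) | {theta2_hat})
    rows = []
    for t in grid:
        ratios = liability_wald_ratios(fit, out, theta2=t)
        ivw = ivw_combine(ratios, model=model, theta2=t)
        gs = c_s * np.sqrt(1.0 - t)
        prs = MrEstimate(method="PRS", theta2=t, estimate=beta_ys / gs, se=se_ys / abs(gs))
        for est in (ivw, prs):
            rows.append(
                {
                    "method": est.method,
                    "theta2": t,
                    "is_estimated": bool(np.isclose(t, theta2_hat)),
                    "log_rr": est.estimate,
                    "se": est.se,
                    "rr": est.rr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                    "Q": het.Q if het else np.nan,
                    "Q_p": het.p if het else np.nan,
                    "model": model,
                }
            )
    return SweepResult(
        fit=fit, lrt=lrt, theta2_hat=theta2_hat, heterogeneity=het, table=pd.DataFrame(rows)
    )
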