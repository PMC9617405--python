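"""Shared fixtures and independent numerical oracles.

The oracle fitters here maximise the relevant log-likelihoods directly
with generic numerical optimisation (Nelder-Mead refined by BFGS on the
raw likelihood), independently of the model-fitting paths used by the
package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from coarsemr.containers import CohortPhenotypes
from coarsemr.pipeline import AnalysisConfig, run_bidirectional
from coarsemr.simulate import bidirectional_test_config, simulate_cohort


# ---------------------------------------------------------------------------
# oracle likelihood maximisers (deliberately naive and generic)
# ---------------------------------------------------------------------------
def _maximise(nll, k):
    best = None
    for x0 in (np.zeros(k), np.full(k, 0.1)):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        res = minimize(nll, res.x, method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def oracle_logistic(y, X):
    """Direct numerical ML for logistic regression coefficients."""
    y, X = np.asarray(y, float), np.asarray(X, float)

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    return _maximise(nll, X.shape[1])


def oracle_probit(y, X):
    """Direct numerical ML for probit regression coefficients."""
    y, X = np.asarray(y, float), np.asarray(X, float)

    def nll(b):
        eta = X @ b
        p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    return _maximise(nll, X.shape[1])


def oracle_poisson_log(y, X):
    """Direct numerical ML for a log-link Poisson working model."""
    y, X = np.asarray(y, float), np.asarray(X, float)

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.exp(eta))

    return _maximise(nll, X.shape[1])


def oracle_bh(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# shared cohorts
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def bidir_cohort():
    """Forward-only causal cohort, n = 20,000 (exposure RR 1.25 on outcome)."""
    return simulate_cohort(bidirectional_test_config(seed=7))


@pytest.fixture(scope="session")
def bidir_report(bidir_cohort):
    """Full bidirectional pipeline run on the forward-only causal cohort."""
    cfg = AnalysisConfig(seed=7)
    ph = CohortPhenotypes(bidir_cohort.phenotypes, binary_traits=("gout", "hypertension"))
    return run_bidirectional(cfg, bidir_cohort.genotypes, ph)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220)


@pytest.fixture()
def tiny_binary_fit_data(rng):
    """30-row dataset with a binary response for oracle-equivalence checks."""
    n = 30
    g = rng.binomial(2, 0.35, size=n).astype(float)
    x = rng.standard_normal(n)
    eta = -0.4 + 0.6 * g - 0.3 * x
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.sum() in (0, n):  # guard: the fixed seed gives both classes
        y[0] = 1 - y[0]
    X = np.column_stack([np.ones(n), g, x])
    return y, X
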