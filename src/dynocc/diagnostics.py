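"""Model validation: convergence, goodness of fit, identifiability, priors.

Convergence uses the classic Gelman-Rubin potential scale reduction
factor (between/within-chain variance comparison; values below 1.1 are
taken as converged) and its multivariate Brooks-Gelman extension over the
coefficient block.  Goodness of fit is a posterior-predictive Bayesian
p-value built on Pearson residuals; identifiability is the percentage
overlap between prior and posterior densities (below 35% counts as
identifiable); prior sensitivity refits the model under alternative
weakly informative coefficient priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .inference import ChainConfig, PosteriorDraws, PriorConfig, fit_dom
from .model_core import (
    CovariateSet,
    DetectionHistory,
    detection_design,
    standardize,
)

__all__ = [
    "DiagnosticsReport",
    "gelman_rubin",
    "gelman_rubin_multivariate",
    "gelman_rubin_report",
    "bayesian_p_value",
    "p_value_from_discrepancies",
    "prior_posterior_overlap",
    "overlap_report",
    "prior_sensitivity",
    "SensitivityResult",
    "diagnostics_report",
]

logger = logging.getLogger(__name__)

_EPS = 1e-6  # Pearson residual variance guard for z=0 cells

RHAT_THRESHOLD = 1.1
OVERLAP_THRESHOLD_PCT = 35.0


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def gelman_rubin(samples) -> float:
    """Potential scale reduction factor for one parameter.

    ``samples`` is (n_chains, n_draws).  Computes ``sqrt(V_hat / W)``
    with ``V_hat = (n-1)/n W + B/n`` from the between- and within-chain
    variances.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = x.shape
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)  # = B / n
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def gelman_rubin_multivariate(samples) -> float:
    """Brooks-Gelman multivariate PSRF over a parameter block.

    ``samples`` is (n_chains, n_draws, n_params); returns
    ``sqrt((n-1)/n + (m+1)/m * lambda_max)`` with ``lambda_max`` the
    largest eigenvalue of ``W^{-1} B/n``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of vector draws")
    m, n, p = x.shape
    w = np.mean([np.cov(x[c], rowvar=False, ddof=1) for c in range(m)], axis=0)
    w = np.atleast_2d(w)
    means = x.mean(axis=1)
    b_over_n = np.atleast_2d(np.cov(means, rowvar=False, ddof=1))
    lam = np.linalg.eigvals(np.linalg.pinv(w) @ b_over_n)
    lam_max = float(np.max(lam.real))
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam_max))


def gelman_rubin_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter R-hat plus the multivariate statistic over the
    coefficient block (flagged row ``__multivariate__``)."""
    rows = [{"parameter": name, "rhat": gelman_rubin(chain),
             "converged": gelman_rubin(chain) < RHAT_THRESHOLD}
            for name, chain in draws.coefficient_chains().items()]
    block = np.concatenate([draws.alpha, draws.beta], axis=2)
    mv = gelman_rubin_multivariate(block)
    rows.append({"parameter": "__multivariate__", "rhat": mv,
                 "converged": mv < RHAT_THRESHOLD})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def p_value_from_discrepancies(d_obs, d_sim) -> float:
    """Fraction of draws whose simulated discrepancy exceeds the observed
    one — the posterior-predictive (Bayesian) p-value."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_sim = np.asarray(d_sim, dtype=float)
    return float(np.mean(d_sim > d_obs))


def bayesian_p_value(draws: PosteriorDraws, data: DetectionHistory,
                     covs: CovariateSet, rng=None, max_draws: int | None = None,
                     return_discrepancies: bool = False):
    """Posterior-predictive goodness of fit via Pearson residuals.

    For each stored draw, a replicate dataset is simulated conditional on
    that draw's latent states and detection probabilities, and the summed
    squared Pearson residual ``r = (y - z p) / sqrt(z p (1 - z p) + eps)``
    is compared between observed and simulated data.  Values near 0.5
    indicate adequate fit.
    """
    rng = rng or np.random.default_rng()
    if not covs.is_standardized:
        covs = standardize(covs)
    Xd_full = detection_design(covs, include_effort=draws.include_effort)
    flat_mask = data.mask.reshape(-1)
    Xd = Xd_full.reshape(-1, Xd_full.shape[-1])[flat_mask]
    sites, seasons, _ = np.nonzero(data.mask)
    y = data.y[data.mask].astype(float)

    A = draws.stacked("alpha")
    W = draws.stacked("w_alpha").astype(float)
    V = W.copy()
    V[:, 0] = 1.0
    V[:, 3] = W[:, 3] * W[:, 1] * W[:, 2]
    Z = draws.stacked("z")
    n_total = A.shape[0]
    use = np.arange(n_total)
    if max_draws is not None and max_draws < n_total:
        use = rng.choice(n_total, size=max_draws, replace=False)

    d_obs = np.empty(use.shape[0])
    d_sim = np.empty(use.shape[0])
    for start in range(0, use.shape[0], 256):
        sel = use[start:start + 256]
        theta = A[sel] * V[sel]
        p = expit(theta @ Xd.T)
        e = p * Z[sel][:, sites, seasons]
        var = e * (1.0 - e) + _EPS
        d_obs[start:start + 256] = (((y - e) ** 2) / var).sum(axis=1)
        y_sim = rng.random(e.shape) < e
        d_sim[start:start + 256] = (((y_sim - e) ** 2) / var).sum(axis=1)
    p_val = p_value_from_discrepancies(d_obs, d_sim)
    if return_discrepancies:
        return p_val, d_obs, d_sim
    return p_val


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------

def prior_posterior_overlap(samples, prior: PriorConfig, n_grid: int = 1024) -> float:
    """Percent overlap between the prior density and a kernel estimate of
    the posterior (Silverman bandwidth, trapezoid integral on a grid
    spanning both densities' 0.0001 quantiles)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 500:
        raise ValueError("need >= 500 draws for a stable overlap estimate")
    kde = gaussian_kde(x, bw_method="silverman")
    lo = min(prior.ppf(1e-4), np.quantile(x, 1e-4))
    hi = max(prior.ppf(1 - 1e-4), np.quantile(x, 1 - 1e-4))
    # widen by the KDE bandwidth so the kernel tails are covered
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(lo - 3 * bw, hi + 3 * bw, n_grid)
    dens_prior = np.exp(prior.logpdf(grid))
    dens_post = kde(grid)
    return float(np.trapezoid(np.minimum(dens_prior, dens_post), grid) * 100.0)


def overlap_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Prior-posterior overlap percent per coefficient; below 35% counts
    as identifiable."""
    rows = []
    a = draws.stacked("alpha")
    for k, term in enumerate(draws.det_terms):
        pct = prior_posterior_overlap(a[:, k], draws.prior)
        rows.append({"submodel": "detection", "parameter": term,
                     "overlap_pct": pct,
                     "identifiable": pct < OVERLAP_THRESHOLD_PCT})
    b = draws.stacked("beta")
    for k, term in enumerate(draws.occ_terms):
        pct = prior_posterior_overlap(b[:, k], draws.prior)
        rows.append({"submodel": "occupancy", "parameter": term,
                     "overlap_pct": pct,
                     "identifiable": pct < OVERLAP_THRESHOLD_PCT})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prior sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Posterior mean/sd per parameter under each prior, plus the largest
    absolute shift in posterior means across priors."""

    table: pd.DataFrame
    max_abs_shift: float


def prior_sensitivity(data: DetectionHistory, covs: CovariateSet, model: str,
                      prior_set: list[PriorConfig], chains: ChainConfig,
                      include_effort: bool = True) -> SensitivityResult:
    """Refit the model under each prior in ``prior_set`` and tabulate the
    posterior means and standard deviations per parameter."""
    if len(prior_set) < 2:
        raise ValueError("need at least two prior configurations")
    frames = []
    for i, prior in enumerate(prior_set):
        draws = fit_dom(data, covs, model=model, prior=prior, chains=chains,
                        include_effort=include_effort)
        tab = draws.summary()[["submodel", "parameter", "mean", "sd"]].copy()
        tab.insert(0, "prior", f"{prior.name}[{i}]")
        frames.append(tab)
        logger.info("sensitivity refit %d/%d (%s) done", i + 1, len(prior_set),
                    prior.name)
    table = pd.concat(frames, ignore_index=True)
    wide = table.pivot_table(index=["submodel", "parameter"], columns="prior",
                             values="mean")
    shift = float((wide.max(axis=1) - wide.min(axis=1)).max())
    return SensitivityResult(table=table, max_abs_shift=shift)


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Validation suite output for one fit."""

    rhat: pd.DataFrame
    multivariate_rhat: float
    bayesian_p: float
    overlap: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        parts = [self.rhat.assign(kind="rhat")]
        parts.append(pd.DataFrame([{"parameter": "bayesian_p_value",
                                    "rhat": np.nan, "converged": np.nan,
                                    "kind": "gof", "value": self.bayesian_p}]))
        ov = self.overlap.rename(columns={"overlap_pct": "value"})
        parts.append(ov.assign(kind="overlap"))
        return pd.concat(parts, ignore_index=True)


def diagnostics_report(draws: PosteriorDraws, data: DetectionHistory,
                       covs: CovariateSet, rng=None,
                       max_gof_draws: int | None = 2000) -> DiagnosticsReport:
    """Run the full validation suite on one fit."""
    rhat = gelman_rubin_report(draws)
    mv = float(rhat.loc[rhat.parameter == "__multivariate__", "rhat"].iloc[0])
    p_val = bayesian_p_value(draws, data, covs, rng=rng, max_draws=max_gof_draws)
    ov = overlap_report(draws)
    logger.info("diagnostics: MV R-hat %.3f, Bayesian p %.3f", mv, p_val)
    return DiagnosticsReport(rhat=rhat, multivariate_rhat=mv,
                             bayesian_p=p_val, overlap=ov)
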