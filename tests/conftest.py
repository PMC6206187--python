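"""Shared fixtures: small covariate factories, the paper-like fit, and the
session-wide replicate recovery study that several checks consume."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynocc
from dynocc.inference import ChainConfig, PosteriorDraws, PRIOR_PRESETS, fit_dom
from dynocc.model_core import CovariateSet, DetectionHistory

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# identity standardization constants: treat covariates as already scaled
STD_IDENTITY = {n: (0.0, 1.0) for n in ("depth", "rdmv", "curmax",
                                        "current", "effort")}

TRUE_RECOVERY_ALPHA = np.array([-1.5, -1.2, 3.0, 1.8])


def make_covs(n_sites, n_seasons, max_reps, rng=None, standardized=True):
    """Random covariate set; marked pre-standardized by default so tiny
    (even single-site) designs can feed the likelihoods directly."""
    rng = rng or np.random.default_rng(0)
    return CovariateSet(
        depth=rng.normal(size=n_sites),
        rdmv=rng.normal(size=n_sites),
        curmax=rng.normal(size=n_sites),
        bottom_type=np.where(rng.random(n_sites) < 0.5, "canopy", "none"),
        current=rng.normal(size=(n_sites, n_seasons, max_reps)),
        effort=rng.normal(size=(n_sites, n_seasons, max_reps)),
        standardization_constants=STD_IDENTITY if standardized else None)


def make_history(y, mask=None, obs_time=None):
    y = np.asarray(y, dtype=np.int8)
    if mask is None:
        mask = np.ones_like(y, dtype=bool)
    return DetectionHistory(y=y, mask=np.asarray(mask, bool), obs_time=obs_time)


def make_draws(z, alpha=None, beta=None, phi=None, gamma=None, w_alpha=None,
               w_beta=None, has_detection=None, include_effort=False,
               constants=None):
    """Hand-built PosteriorDraws for derived-quantity arithmetic tests.

    ``z`` is (n_draws, n_sites, n_seasons); scalar blocks are tiled.
    """
    z = np.asarray(z, dtype=np.uint8)[None]  # one chain
    s, n, t = z.shape[1:]
    ka = 5 if include_effort else 4

    def tile(x, k, default=0.0):
        if x is None:
            x = np.full(k, default)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = np.broadcast_to(x, (s, k))
        return x[None].copy()

    alpha = tile(alpha, ka)
    beta = tile(beta, 1)
    phi = tile(phi, t - 1, 0.5)
    gamma = tile(gamma, t - 1, 0.5)
    w_alpha = tile(w_alpha, ka, 1.0).astype(np.int8)
    w_beta = tile(w_beta, 1, 1.0).astype(np.int8)
    if has_detection is None:
        has_detection = np.zeros((n, t), bool)
    return PosteriorDraws(
        alpha=alpha, beta=beta, phi=phi, gamma=gamma, w_alpha=w_alpha,
        w_beta=w_beta, z=z, has_detection=np.asarray(has_detection, bool),
        model="A", include_effort=include_effort,
        prior=PRIOR_PRESETS["dorazio"],
        chains=ChainConfig(n_chains=1, n_draws=s, burn_in=0, thin=1),
        standardization_constants=constants or dict(STD_IDENTITY))


SCALED_CHAINS = ChainConfig(n_chains=4, n_draws=4000, burn_in=1000,
                            thin=10, seed=11)


@pytest.fixture(scope="session")
def paper_fit():
    """Model A fitted to the default study-shaped fixture at desk-scale
    chain settings."""
    truth = dynocc.paper_like_truth(0)
    cfg = ChainConfig(n_chains=4, n_draws=4000, burn_in=1500, thin=5, seed=11)
    draws = fit_dom(truth.history, truth.covs, model="A", chains=cfg)
    return truth, draws


@pytest.fixture(scope="session")
def recovery_study():
    """Twenty replicate simulate-and-fit runs at 200 sites x 4 seasons x 3
    replicates with a strong detection structure and a null effort term.

    Returns per-replicate posterior summaries plus the first replicate's
    full draws for surface-shape checks.
    """
    results = []
    first = None
    for rep in range(20):
        truth = dynocc.recovery_truth(rep)
        cfg = ChainConfig(n_chains=4, n_draws=4000, burn_in=1000, thin=10,
                          seed=1000 + rep)
        draws = fit_dom(truth.history, truth.covs, model="A", chains=cfg)
        a = draws.stacked("alpha")
        incl = dynocc.inclusion_summary(draws)
        det = incl[incl.submodel == "detection"].set_index("parameter")
        gof = dynocc.bayesian_p_value(
            draws, truth.history, truth.covs,
            rng=np.random.default_rng(5000 + rep), max_draws=800)
        results.append({
            "mean": a.mean(axis=0),
            "lo": np.percentile(a, 2.5, axis=0),
            "hi": np.percentile(a, 97.5, axis=0),
            "inclusion": det["inclusion_mean"].to_dict(),
            "gof": gof,
        })
        if rep == 0:
            first = (truth, draws)
    return {"replicates": results, "first": first}
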