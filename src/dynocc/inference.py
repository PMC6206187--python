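"""Metropolis-within-Gibbs sampler for the dynamic occupancy model.

The sampler augments the posterior with the latent occupancy states
``z[site, season]`` and cycles:

1. ``z`` by forward-filter backward-sampling of each site's two-state
   occupancy chain (exact joint draw given the current parameters),
2. ``phi``/``gamma`` by conjugate Beta draws from the latent transition
   counts (uniform prior -> Beta(1 + successes, 1 + failures)),
3. occupancy and detection coefficients by per-coefficient random-walk
   Metropolis against the complete-data likelihood, with proposal scales
   adapted only during burn-in,
4. inclusion indicators ``w_k ~ Bernoulli(0.5)`` by Gibbs draws in the
   Kuo-Mallick scheme: an excluded coefficient is resampled from its
   prior (the pseudo-prior), so the conditional odds of inclusion reduce
   to the likelihood ratio with the term in versus out.  The detection
   interaction only enters the likelihood when both parent indicators are
   on (Kruschke product rule).

Coefficients take weakly informative scaled-t priors (default mu = 0,
sigma = 1.566, nu = 7.763); phi and gamma are uniform on [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import t as t_dist

from .model_core import (
    CovariateSet,
    DetectionHistory,
    DOMParams,
    LatentStates,
    OCC_TERMS,
    DET_TERMS,
    detection_design,
    effective_w_alpha,
    occupancy_design,
    occupancy_prob,
    standardize,
)

__all__ = [
    "PriorConfig",
    "PRIOR_PRESETS",
    "ChainConfig",
    "PosteriorDraws",
    "log_prior",
    "sample_latent_z",
    "fit_dom",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# priors and chain settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Scaled-t prior for logit-scale coefficients.

    ``phi``/``gamma`` always take uniform [0, 1] priors and each inclusion
    indicator a Bernoulli(0.5) prior; only the coefficient prior varies.
    """

    mu: float = 0.0
    sigma: float = 1.566
    nu: float = 7.763
    name: str = "dorazio"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.nu <= 0:
            raise ValueError("prior sigma and nu must be positive")

    def logpdf(self, x):
        return t_dist.logpdf(x, df=self.nu, loc=self.mu, scale=self.sigma)

    def rvs(self, size=None, rng=None):
        rng = rng or np.random.default_rng()
        return self.mu + self.sigma * rng.standard_t(self.nu, size=size)

    def ppf(self, q):
        return t_dist.ppf(q, df=self.nu, loc=self.mu, scale=self.sigma)


# The three coefficient priors used in the sensitivity analysis.  The
# Jeffreys/Firth member is its scaled-t approximation; no data-dependent
# Jeffreys prior is computed.
PRIOR_PRESETS = {
    "dorazio": PriorConfig(0.0, 1.566, 7.763, "dorazio"),
    "firth_t": PriorConfig(0.0, 2.5, 7.0, "firth_t"),
    "gelman": PriorConfig(0.0, 2.5, 1.0, "gelman"),
}


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings; defaults match the full-scale analysis
    (5 chains x 50,000 draws, 10,000 burn-in, thin 10)."""

    n_chains: int = 5
    n_draws: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    initial_step: float = 0.4
    adapt_interval: int = 100
    accept_low: float = 0.2
    accept_high: float = 0.5
    init_scale_mult: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("require 0 <= burn_in < n_draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_draws - self.burn_in + self.thin - 1) // self.thin


def log_prior(params: DOMParams, prior: PriorConfig) -> float:
    """Joint log prior density/mass of one parameter state.

    Scaled-t density for the intercepts and every included (w=1)
    coefficient, log(1/2) mass per non-intercept indicator, flat inside
    [0, 1] for phi/gamma and -inf outside.
    """
    if not params.in_support():
        return -math.inf
    total = 0.0
    for coef, w in ((params.alpha, params.w_alpha), (params.beta, params.w_beta)):
        keep = np.asarray(w, bool).copy()
        keep[0] = True
        total += float(prior.logpdf(coef[keep]).sum())
        total += math.log(0.5) * (coef.shape[0] - 1)
    return total


# ---------------------------------------------------------------------------
# latent-state sampling
# ---------------------------------------------------------------------------

def _ffbs(psi, phi, gamma, em1, em0, rng) -> np.ndarray:
    """Joint draw of z for all sites by forward filtering / backward
    sampling of the two-state chain, vectorized over sites."""
    N, T = em1.shape
    m = np.maximum(em0, em1)
    e0 = np.exp(em0 - m)
    e1 = np.exp(em1 - m)
    f1 = np.empty((T, N))
    a1 = psi * e1[:, 0]
    a0 = (1.0 - psi) * e0[:, 0]
    f1[0] = a1 / (a0 + a1)
    for t in range(1, T):
        pred1 = f1[t - 1] * phi[t - 1] + (1.0 - f1[t - 1]) * gamma[t - 1]
        a1 = pred1 * e1[:, t]
        a0 = (1.0 - pred1) * e0[:, t]
        f1[t] = a1 / (a0 + a1)
    z = np.empty((N, T), dtype=np.int8)
    u = rng.random((N, T))
    z[:, T - 1] = u[:, T - 1] < f1[T - 1]
    for t in range(T - 2, -1, -1):
        zn = z[:, t + 1]
        m1 = np.where(zn == 1, phi[t], 1.0 - phi[t])
        m0 = np.where(zn == 1, gamma[t], 1.0 - gamma[t])
        a1 = f1[t] * m1
        a0 = (1.0 - f1[t]) * m0
        z[:, t] = u[:, t] < a1 / (a1 + a0)
    return z


def sample_latent_z(params: DOMParams, data: DetectionHistory,
                    covs: CovariateSet, rng=None) -> LatentStates:
    """One exact draw of the latent occupancy states given parameters.

    Site-seasons with a detection are occupied with probability 1; the
    rest are drawn from the full conditional combining the temporal
    neighbours (via phi/gamma), initial occupancy, and the probability of
    the all-zero replicate record.
    """
    from .model_core import _site_emissions  # local import to keep surface tidy
    rng = rng or np.random.default_rng()
    if not covs.is_standardized:
        covs = standardize(covs)
    em1, em0 = _site_emissions(params, data, covs)
    psi = np.broadcast_to(
        occupancy_prob(params, covs.depth, covs.rdmv, covs.curmax),
        (data.n_sites,)).astype(float)
    phi = params.phi if data.n_seasons > 1 else np.empty(0)
    gamma = params.gamma if data.n_seasons > 1 else np.empty(0)
    return LatentStates(_ffbs(psi, phi, gamma, em1, em0, rng))


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in MCMC samples, organized by chain."""

    alpha: np.ndarray        # (chains, stored, K_det)
    beta: np.ndarray         # (chains, stored, K_occ)
    phi: np.ndarray          # (chains, stored, T-1)
    gamma: np.ndarray        # (chains, stored, T-1)
    w_alpha: np.ndarray      # (chains, stored, K_det) int8
    w_beta: np.ndarray       # (chains, stored, K_occ) int8
    z: np.ndarray            # (chains, stored, n_sites, T) uint8
    has_detection: np.ndarray
    model: str
    include_effort: bool
    prior: PriorConfig
    chains: ChainConfig
    standardization_constants: dict
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_stored(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_seasons(self) -> int:
        return self.z.shape[3]

    @property
    def det_terms(self) -> tuple[str, ...]:
        return DET_TERMS if self.include_effort else DET_TERMS[:4]

    @property
    def occ_terms(self) -> tuple[str, ...]:
        return OCC_TERMS if self.model == "B" else OCC_TERMS[:1]

    def stacked(self, name: str) -> np.ndarray:
        """Samples with chains concatenated: (n_chains * n_stored, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def effective_w_interaction(self) -> np.ndarray:
        """Stacked effective inclusion of the current x none interaction
        (product of its indicator with both parents')."""
        w = self.stacked("w_alpha")
        return w[:, 3] * w[:, 1] * w[:, 2]

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/2.5-50-97.5% and inclusion probability per
        parameter, shaped like a fitted-coefficients table."""
        rows = []

        def add(submodel, name, samples, incl):
            q = np.percentile(samples, [2.5, 50.0, 97.5])
            rows.append({
                "submodel": submodel, "parameter": name,
                "mean": samples.mean(), "sd": samples.std(ddof=1),
                "q2.5": q[0], "median": q[1], "q97.5": q[2],
                "inclusion_prob": incl,
            })

        a = self.stacked("alpha")
        wa = self.stacked("w_alpha")
        for k, term in enumerate(self.det_terms):
            if k == 0:
                incl = np.nan
            elif term == "current_none":
                incl = float(self.effective_w_interaction().mean())
            else:
                incl = float(wa[:, k].mean())
            add("detection", term, a[:, k], incl)
        b = self.stacked("beta")
        wb = self.stacked("w_beta")
        for k, term in enumerate(self.occ_terms):
            incl = np.nan if k == 0 else float(wb[:, k].mean())
            add("occupancy", term, b[:, k], incl)
        ph = self.stacked("phi")
        ga = self.stacked("gamma")
        for t in range(ph.shape[1]):
            add("dynamics", f"phi_{t + 1}_{t + 2}", ph[:, t], np.nan)
            add("dynamics", f"gamma_{t + 1}_{t + 2}", ga[:, t], np.nan)
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) frame of the non-latent
        parameters."""
        frames = []
        names = {
            "alpha": [f"alpha_{t}" for t in self.det_terms],
            "beta": [f"beta_{t}" for t in self.occ_terms],
            "w_alpha": [f"w_alpha_{t}" for t in self.det_terms],
            "w_beta": [f"w_beta_{t}" for t in self.occ_terms],
            "phi": [f"phi_{t + 1}_{t + 2}" for t in range(self.phi.shape[2])],
            "gamma": [f"gamma_{t + 1}_{t + 2}" for t in range(self.gamma.shape[2])],
        }
        for attr, cols in names.items():
            arr = getattr(self, attr)
            for k, col in enumerate(cols):
                for c in range(self.n_chains):
                    frames.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(self.n_stored),
                        "parameter": col, "value": arr[c, :, k],
                    }))
        return pd.concat(frames, ignore_index=True)

    def coefficient_chains(self) -> dict[str, np.ndarray]:
        """Per-parameter (n_chains, n_stored) sample arrays for the
        coefficient block plus phi/gamma — convergence-diagnostic input."""
        out = {}
        for k, term in enumerate(self.det_terms):
            out[f"alpha_{term}"] = self.alpha[:, :, k]
        for k, term in enumerate(self.occ_terms):
            out[f"beta_{term}"] = self.beta[:, :, k]
        for t in range(self.phi.shape[2]):
            out[f"phi_{t + 1}_{t + 2}"] = self.phi[:, :, t]
            out[f"gamma_{t + 1}_{t + 2}"] = self.gamma[:, :, t]
        return out

    def save(self, path) -> None:
        meta = {
            "model": self.model, "include_effort": self.include_effort,
            "prior": dataclasses.asdict(self.prior),
            "chains": dataclasses.asdict(self.chains),
            "standardization_constants": self.standardization_constants,
            "acceptance": self.acceptance,
        }
        np.savez_compressed(
            path, alpha=self.alpha, beta=self.beta, phi=self.phi,
            gamma=self.gamma, w_alpha=self.w_alpha, w_beta=self.w_beta,
            z=self.z, has_detection=self.has_detection,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
            return cls(
                alpha=npz["alpha"], beta=npz["beta"], phi=npz["phi"],
                gamma=npz["gamma"], w_alpha=npz["w_alpha"],
                w_beta=npz["w_beta"], z=npz["z"],
                has_detection=npz["has_detection"],
                model=meta["model"], include_effort=meta["include_effort"],
                prior=PriorConfig(**meta["prior"]),
                chains=ChainConfig(**meta["chains"]),
                standardization_constants={
                    k: tuple(v) for k, v in
                    meta["standardization_constants"].items()},
                acceptance=meta["acceptance"])


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _bern_ll(y_dot_eta_terms, eta):
    # sum_i y_i eta_i - log(1 + exp(eta_i)) over the z=1 observations
    return y_dot_eta_terms @ eta - np.logaddexp(0.0, eta).sum()


def _run_chain(y, Xd, site_idx, season_idx, cell, has_det, Xo, n_sites, T,
               prior: PriorConfig, cfg: ChainConfig, rng, fixed):
    K = Xd.shape[1]
    Kb = Xo.shape[1]
    mu, sigma, nu = prior.mu, prior.sigma, prior.nu
    tconst = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
              - 0.5 * math.log(nu * math.pi) - math.log(sigma))
    half = 0.5 * (nu + 1)

    def tlp(x: float) -> float:
        s = (x - mu) / sigma
        return tconst - half * math.log1p(s * s / nu)

    def prior_draw() -> float:
        return mu + sigma * rng.standard_t(nu)

    fixed = fixed or {}
    upd_alpha = np.asarray(fixed.get("update_alpha", np.ones(K, bool)), bool)
    upd_beta = np.asarray(fixed.get("update_beta", np.ones(Kb, bool)), bool)

    # over-dispersed initialization: coefficients at twice the prior scale
    alpha = np.asarray(fixed.get(
        "alpha", mu + cfg.init_scale_mult * sigma * rng.standard_t(nu, K)), float).copy()
    beta = np.asarray(fixed.get(
        "beta", mu + cfg.init_scale_mult * sigma * rng.standard_t(nu, Kb)), float).copy()
    n_int = max(T - 1, 0)
    phi = np.asarray(fixed.get("phi", rng.uniform(size=n_int)), float).copy()
    gamma = np.asarray(fixed.get("gamma", rng.uniform(size=n_int)), float).copy()
    w_a = np.asarray(fixed.get("w_alpha", np.ones(K)), np.int8).copy()
    w_b = np.asarray(fixed.get("w_beta", np.ones(Kb)), np.int8).copy()
    upd_phi = "phi" not in fixed
    upd_gamma = "gamma" not in fixed
    upd_wa = "w_alpha" not in fixed
    upd_wb = "w_beta" not in fixed and Kb > 1

    def v_of_wa(w):
        v = w.astype(float)
        v[0] = 1.0
        if K >= 4:
            v[3] = v[3] * v[1] * v[2]
        return v

    def v_of_wb(w):
        v = w.astype(float)
        v[0] = 1.0
        return v

    v_a = v_of_wa(w_a)
    v_b = v_of_wb(w_b)

    step_a = np.full(K, cfg.initial_step)
    step_b = np.full(Kb, cfg.initial_step)
    acc_a = np.zeros(K)
    try_a = np.zeros(K)
    acc_b = np.zeros(Kb)
    try_b = np.zeros(Kb)
    acc_post = np.zeros(2)  # accepted, proposed after burn-in

    n_store = cfg.n_stored
    S = {
        "alpha": np.empty((n_store, K)), "beta": np.empty((n_store, Kb)),
        "phi": np.empty((n_store, n_int)), "gamma": np.empty((n_store, n_int)),
        "w_alpha": np.empty((n_store, K), np.int8),
        "w_beta": np.empty((n_store, Kb), np.int8),
        "z": np.empty((n_store, n_sites, T), np.uint8),
    }
    em0 = np.where(has_det, -np.inf, 0.0)
    n_cells = n_sites * T
    s_idx = 0

    for it in range(cfg.n_draws):
        # --- latent states -------------------------------------------------
        eta_all = Xd @ (alpha * v_a)
        ll_terms = y * eta_all - np.logaddexp(0.0, eta_all)
        em1 = np.bincount(cell, ll_terms, minlength=n_cells).reshape(n_sites, T)
        eta_o = Xo @ (beta * v_b)
        psi = expit(eta_o)
        z = _ffbs(psi, phi, gamma, em1, em0, rng)

        # --- phi / gamma: conjugate Beta given transition counts -----------
        if T > 1 and (upd_phi or upd_gamma):
            z0 = z[:, :-1]
            z1 = z[:, 1:]
            occ = z0 == 1
            n11 = (occ & (z1 == 1)).sum(axis=0)
            n1 = occ.sum(axis=0)
            n01 = (~occ & (z1 == 1)).sum(axis=0)
            n0 = n_sites - n1
            if upd_phi:
                phi = rng.beta(1.0 + n11, 1.0 + n1 - n11)
            if upd_gamma:
                gamma = rng.beta(1.0 + n01, 1.0 + n0 - n01)

        # --- occupancy coefficients ----------------------------------------
        zf = z[:, 0].astype(float)
        llb = _bern_ll(zf, eta_o)
        for k in range(Kb):
            if not upd_beta[k]:
                continue
            if v_b[k] == 0.0 and k > 0:
                beta[k] = prior_draw()  # pseudo-prior for the excluded term
                continue
            prop = beta[k] + step_b[k] * rng.standard_normal()
            eta_new = eta_o + (prop - beta[k]) * Xo[:, k]
            lln = _bern_ll(zf, eta_new)
            try_b[k] += 1
            if it >= cfg.burn_in:
                acc_post[1] += 1
            if math.log(rng.random()) < lln - llb + tlp(prop) - tlp(beta[k]):
                beta[k] = prop
                eta_o = eta_new
                llb = lln
                acc_b[k] += 1
                if it >= cfg.burn_in:
                    acc_post[0] += 1
        if upd_wb:
            for k in range(1, Kb):
                alt = w_b.copy()
                alt[k] = 1 - alt[k]
                eta_alt = Xo @ (beta * v_of_wb(alt))
                ll_alt = _bern_ll(zf, eta_alt)
                diff = (ll_alt - llb) if w_b[k] == 0 else (llb - ll_alt)
                # diff = ll(in) - ll(out); prior odds are 1
                p_in = 1.0 / (1.0 + math.exp(-max(min(diff, 700.0), -700.0)))
                new = np.int8(rng.random() < p_in)
                if new != w_b[k]:
                    w_b[k] = new
                    llb = ll_alt
                    eta_o = eta_alt
            v_b = v_of_wb(w_b)

        # --- detection coefficients (z=1 observations only) -----------------
        zobs = z[site_idx, season_idx] == 1
        idx = np.flatnonzero(zobs)
        yz = y[idx]
        Xz = Xd[idx]
        eta_z = Xz @ (alpha * v_a)
        lla = _bern_ll(yz, eta_z)
        for k in range(K):
            if not upd_alpha[k]:
                continue
            if v_a[k] == 0.0 and k > 0:
                alpha[k] = prior_draw()
                continue
            prop = alpha[k] + step_a[k] * rng.standard_normal()
            eta_new = eta_z + (prop - alpha[k]) * v_a[k] * Xz[:, k]
            lln = _bern_ll(yz, eta_new)
            try_a[k] += 1
            if it >= cfg.burn_in:
                acc_post[1] += 1
            if math.log(rng.random()) < lln - lla + tlp(prop) - tlp(alpha[k]):
                alpha[k] = prop
                eta_z = eta_new
                lla = lln
                acc_a[k] += 1
                if it >= cfg.burn_in:
                    acc_post[0] += 1
        if upd_wa:
            for k in range(1, K):
                alt = w_a.copy()
                alt[k] = 1 - alt[k]
                eta_alt = Xz @ (alpha * v_of_wa(alt))
                ll_alt = _bern_ll(yz, eta_alt)
                diff = (ll_alt - lla) if w_a[k] == 0 else (lla - ll_alt)
                p_in = 1.0 / (1.0 + math.exp(-max(min(diff, 700.0), -700.0)))
                new = np.int8(rng.random() < p_in)
                if new != w_a[k]:
                    w_a[k] = new
                    lla = ll_alt
                    eta_z = eta_alt
            v_a = v_of_wa(w_a)

        # --- proposal-scale adaptation, burn-in only ------------------------
        if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
            for steps, acc, tries in ((step_a, acc_a, try_a), (step_b, acc_b, try_b)):
                with np.errstate(invalid="ignore"):
                    rate = np.where(tries > 0, acc / np.maximum(tries, 1), np.nan)
                steps[rate < cfg.accept_low] *= 0.7
                steps[rate > cfg.accept_high] *= 1.4
            acc_a[:] = 0
            try_a[:] = 0
            acc_b[:] = 0
            try_b[:] = 0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            S["alpha"][s_idx] = alpha
            S["beta"][s_idx] = beta
            S["phi"][s_idx] = phi
            S["gamma"][s_idx] = gamma
            S["w_alpha"][s_idx] = w_a
            S["w_beta"][s_idx] = w_b
            S["z"][s_idx] = z
            s_idx += 1

    rate = acc_post[0] / acc_post[1] if acc_post[1] else float("nan")
    return S, rate


def fit_dom(data: DetectionHistory, covs: CovariateSet, model: str = "A",
            prior: PriorConfig | None = None, chains: ChainConfig | None = None,
            include_effort: bool = True, fixed: dict | None = None) -> PosteriorDraws:
    """Fit the dynamic occupancy model by MCMC.

    ``model="A"`` uses a covariate-free (intercept-only) initial-occupancy
    submodel; ``model="B"`` adds depth, RDMV, curmax and curmax^2.  Both
    share the detection submodel (current, bottom type, interaction,
    optionally effort).  Runs ``chains.n_chains`` independent chains with
    over-dispersed starts and returns the thinned post-burn-in draws.

    ``fixed`` optionally pins parameter blocks (keys ``alpha``, ``beta``,
    ``phi``, ``gamma``, ``w_alpha``, ``w_beta``, plus boolean masks
    ``update_alpha``/``update_beta``) — used for conditional-posterior
    validation.

    With a completely empty replicate record the posterior is the prior
    and the sampler simply reproduces it; otherwise at least one
    site-season must hold more than one replicate.
    """
    if model not in ("A", "B"):
        raise ValueError("model must be 'A' or 'B'")
    prior = prior or PRIOR_PRESETS["dorazio"]
    chains = chains or ChainConfig()
    if data.mask.any() and not data.has_multi_replicate():
        raise ValueError("the model requires at least one site-season with "
                         "more than one replicate survey")
    if not covs.is_standardized:
        covs = standardize(covs)
    if covs.current.shape != data.y.shape:
        raise ValueError("covariates and detection history are misaligned")

    Xo_full = occupancy_design(covs)
    Xo = Xo_full if model == "B" else Xo_full[:, :1]
    Xd_full = detection_design(covs, include_effort=include_effort)
    flat_mask = data.mask.reshape(-1)
    Xd = Xd_full.reshape(-1, Xd_full.shape[-1])[flat_mask]
    sites, seasons, reps = np.nonzero(data.mask)
    y = data.y[data.mask].astype(float)
    cell = sites * data.n_seasons + seasons

    seeds = np.random.SeedSequence(chains.seed).spawn(chains.n_chains)
    per_chain = []
    rates = []
    for c in range(chains.n_chains):
        rng = np.random.default_rng(seeds[c])
        S, rate = _run_chain(y, Xd, sites, seasons, cell, data.has_detection,
                             Xo, data.n_sites, data.n_seasons, prior, chains,
                             rng, fixed)
        per_chain.append(S)
        rates.append(rate)
        logger.info("chain %d/%d done, post-burn-in acceptance %.3f",
                    c + 1, chains.n_chains, rate)

    def stack(name):
        return np.stack([S[name] for S in per_chain])

    draws = PosteriorDraws(
        alpha=stack("alpha"), beta=stack("beta"), phi=stack("phi"),
        gamma=stack("gamma"), w_alpha=stack("w_alpha"), w_beta=stack("w_beta"),
        z=stack("z"), has_detection=data.has_detection, model=model,
        include_effort=include_effort, prior=prior, chains=chains,
        standardization_constants=dict(covs.standardization_constants),
        acceptance={"metropolis": float(np.nanmean(rates))})
    for name in ("alpha", "beta", "phi", "gamma"):
        if not np.isfinite(getattr(draws, name)).all():
            raise RuntimeError(f"NaN/inf in posterior draws of {name}; "
                               "check the data and proposal scales")
    return draws
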