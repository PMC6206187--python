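"""Core data structures and likelihoods for the dynamic occupancy model.

The model follows the standard multi-season (dynamic) site-occupancy
parameterization: each site ``i`` carries a latent binary occupancy state
``z[i, t]`` per season ``t``,

* ``z[i, 1] ~ Bernoulli(psi_i)``  (initial occupancy),
* ``z[i, t+1] ~ Bernoulli(z[i, t] * phi_t + (1 - z[i, t]) * gamma_t)``
  (persistence ``phi`` / colonization ``gamma``, constant across sites
  within a between-season interval),
* ``y[i, t, j] ~ Bernoulli(z[i, t] * p[i, t, j])`` for replicate survey
  ``j`` (imperfect detection).

Initial occupancy is modelled on the logit scale from site covariates
(depth, terrain complexity as RDMV, seasonal maximum current and its
square); detection is modelled from replicate covariates (bottom current
speed at observation time, a canopy-absent bottom-type indicator, their
interaction, and optionally sampling effort).  All continuous covariates
are standardized before entering a linear predictor, and every
non-intercept coefficient carries a binary inclusion indicator ``w``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logit as _sp_logit

__all__ = [
    "DET_TERMS",
    "OCC_TERMS",
    "DetectionHistory",
    "CovariateSet",
    "DOMParams",
    "LatentStates",
    "inv_logit",
    "logit",
    "standardize",
    "apply_standardization",
    "occupancy_design",
    "detection_design",
    "effective_w_alpha",
    "occupancy_prob",
    "detection_prob",
    "complete_data_loglik",
    "marginal_loglik",
    "brute_force_loglik",
    "recursive_occupancy",
]

# Design-matrix column order.  Detection: the interaction current x none sits
# at index 3 and is only active when both parents are in (Kruschke product
# rule); effort is an optional trailing column.
DET_TERMS = ("intercept", "current", "none", "current_none", "effort")
OCC_TERMS = ("intercept", "depth", "rdmv", "curmax", "curmax2")

_BRUTE_FORCE_MAX_CELLS = 16


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------

def inv_logit(x):
    """Inverse logit (logistic) link, ``1 / (1 + exp(-x))``.

    Saturates gracefully to 0 or 1 for large ``|x|``.
    """
    return expit(x)


def logit(p):
    """Logit link, ``log(p / (1 - p))``."""
    return _sp_logit(p)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Ragged binary detection records ``y[site, season, replicate]``.

    ``mask`` flags which replicate slots exist; ``y`` is only meaningful
    where ``mask`` is True.  ``obs_time`` holds the observation timestamp
    in seconds since simulation start (NaN where masked).
    """

    y: np.ndarray
    mask: np.ndarray
    obs_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.ndim != 3 or self.mask.shape != self.y.shape:
            raise ValueError("y and mask must be (n_sites, n_seasons, max_reps) arrays")
        if self.obs_time is not None:
            self.obs_time = np.asarray(self.obs_time, dtype=float)
            if self.obs_time.shape != self.y.shape:
                raise ValueError("obs_time must match y's shape")
        if not np.isin(self.y[self.mask], (0, 1)).all():
            raise ValueError("y must be 0/1 wherever mask is True")
        # a completely empty record is allowed (prior-only runs); otherwise
        # every site must contribute at least one replicate somewhere
        if self.mask.any() and not self.mask.any(axis=(1, 2)).all():
            raise ValueError("every site needs at least one replicate in some season")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.y.shape[1]

    @property
    def max_reps(self) -> int:
        return self.y.shape[2]

    @property
    def has_detection(self) -> np.ndarray:
        """Boolean (n_sites, n_seasons): any detection at the site-season."""
        return ((self.y == 1) & self.mask).any(axis=2)

    @property
    def n_reps(self) -> np.ndarray:
        """Replicate counts per (site, season)."""
        return self.mask.sum(axis=2)

    def has_multi_replicate(self) -> bool:
        """True if at least one site-season holds more than one replicate."""
        return bool((self.n_reps > 1).any())


@dataclass
class CovariateSet:
    """Site-level and replicate-level predictors.

    Site-level: ``depth`` (m, negative down), ``rdmv`` (dimensionless
    terrain complexity), ``curmax`` (m/s, seasonal maximum current) and
    ``bottom_type`` (strings ``"canopy"``/``"none"``, site-constant).
    Replicate-level, aligned with a :class:`DetectionHistory`:
    ``current`` (m/s at observation time) and ``effort`` (minutes of
    bottom time), NaN where the replicate slot is masked.

    ``standardization_constants`` maps covariate name -> (mean, sd) once
    :func:`standardize` has run; continuous fields then hold z-scores.
    """

    depth: np.ndarray
    rdmv: np.ndarray
    curmax: np.ndarray
    bottom_type: np.ndarray
    current: np.ndarray
    effort: np.ndarray
    standardization_constants: Mapping[str, tuple[float, float]] | None = None

    CONTINUOUS_SITE = ("depth", "rdmv", "curmax")
    CONTINUOUS_REP = ("current", "effort")

    def __post_init__(self) -> None:
        for name in ("depth", "rdmv", "curmax"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.bottom_type = np.asarray(self.bottom_type)
        self.current = np.asarray(self.current, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        n = self.depth.shape[0]
        if not (self.rdmv.shape[0] == self.curmax.shape[0] == self.bottom_type.shape[0] == n):
            raise ValueError("site-level covariates must share the site dimension")
        if self.current.shape != self.effort.shape or self.current.shape[0] != n:
            raise ValueError("replicate-level covariates must be (n_sites, n_seasons, max_reps)")
        bad = set(np.unique(self.bottom_type)) - {"canopy", "none"}
        if bad:
            raise ValueError(f"unknown bottom_type values: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.depth.shape[0]

    @property
    def none_indicator(self) -> np.ndarray:
        """0/1 per site: 1 where no canopy-forming algae are present."""
        return (self.bottom_type == "none").astype(float)

    @property
    def is_standardized(self) -> bool:
        return self.standardization_constants is not None


@dataclass
class DOMParams:
    """One parameter state of the dynamic occupancy model.

    ``alpha`` are detection coefficients in :data:`DET_TERMS` order
    (effort entry optional), ``beta`` occupancy coefficients in
    :data:`OCC_TERMS` order (a length-1 ``beta`` means an intercept-only,
    covariate-free occupancy submodel).  ``phi``/``gamma`` are per-interval
    persistence/colonization probabilities, length ``n_seasons - 1``.
    ``w_alpha``/``w_beta`` are 0/1 inclusion indicators aligned with the
    coefficients; intercept entries are fixed at 1.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    w_alpha: np.ndarray | None = None
    w_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.w_alpha is None:
            self.w_alpha = np.ones(self.alpha.shape[0], dtype=np.int8)
        if self.w_beta is None:
            self.w_beta = np.ones(self.beta.shape[0], dtype=np.int8)
        self.w_alpha = np.atleast_1d(np.asarray(self.w_alpha, dtype=np.int8))
        self.w_beta = np.atleast_1d(np.asarray(self.w_beta, dtype=np.int8))
        if self.w_alpha.shape != self.alpha.shape or self.w_beta.shape != self.beta.shape:
            raise ValueError("inclusion indicators must align with coefficients")
        if self.phi.shape != self.gamma.shape:
            raise ValueError("phi and gamma must share length n_seasons - 1")

    def in_support(self) -> bool:
        """True when phi and gamma lie in [0, 1] elementwise."""
        return bool(((self.phi >= 0) & (self.phi <= 1)).all()
                    and ((self.gamma >= 0) & (self.gamma <= 1)).all())

    @property
    def include_effort(self) -> bool:
        return self.alpha.shape[0] == len(DET_TERMS)

    @property
    def n_seasons(self) -> int:
        return self.phi.shape[0] + 1


@dataclass
class LatentStates:
    """Binary occupancy ``z[site, season]``."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        if self.z.ndim != 2:
            raise ValueError("z must be (n_sites, n_seasons)")

    def consistent_with(self, data: DetectionHistory) -> bool:
        """Detection implies occupancy: z=1 wherever any y=1."""
        return bool((self.z[data.has_detection] == 1).all())


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _mean_sd(values: np.ndarray, name: str) -> tuple[float, float]:
    obs = values[np.isfinite(values)]
    if obs.size < 2 or np.unique(obs).size < 2:
        raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
    return float(obs.mean()), float(obs.std(ddof=1))


def standardize(covs: CovariateSet) -> CovariateSet:
    """Center and scale every continuous covariate to mean 0, sample SD 1.

    Constants are computed over the sites (site-level covariates) or over
    all observed replicate records (replicate-level covariates, i.e. the
    finite entries) and stored on the returned set for later prediction.
    Categorical ``bottom_type`` is untouched.
    """
    constants: dict[str, tuple[float, float]] = {}
    new = {}
    for name in CovariateSet.CONTINUOUS_SITE + CovariateSet.CONTINUOUS_REP:
        values = getattr(covs, name)
        mean, sd = _mean_sd(values, name)
        constants[name] = (mean, sd)
        new[name] = (values - mean) / sd
    return replace(covs, standardization_constants=constants, **new)


def apply_standardization(values, name: str,
                          constants: Mapping[str, tuple[float, float]]):
    """Standardize new values with stored fit-time constants."""
    if constants is None or name not in constants:
        raise ValueError(f"no stored standardization constants for {name!r}")
    mean, sd = constants[name]
    return (np.asarray(values, dtype=float) - mean) / sd


def _require_standardized(covs: CovariateSet) -> None:
    if not covs.is_standardized:
        raise ValueError("covariates must be standardized first (see standardize())")


# ---------------------------------------------------------------------------
# design matrices and linear predictors
# ---------------------------------------------------------------------------

def occupancy_design(covs: CovariateSet) -> np.ndarray:
    """Site-level design matrix [1, depth, rdmv, curmax, curmax^2].

    The quadratic column is the square of the *standardized* curmax, so
    the quadratic term is centered.
    """
    _require_standardized(covs)
    return np.column_stack([
        np.ones(covs.n_sites),
        covs.depth,
        covs.rdmv,
        covs.curmax,
        covs.curmax ** 2,
    ])


def detection_design(covs: CovariateSet, include_effort: bool = True) -> np.ndarray:
    """Replicate-level design (n_sites, n_seasons, max_reps, K).

    Columns follow :data:`DET_TERMS`; masked replicate slots carry NaN in
    their continuous columns and should be excluded via the mask.
    """
    _require_standardized(covs)
    none = covs.none_indicator[:, None, None] * np.ones_like(covs.current)
    cols = [np.ones_like(covs.current), covs.current, none, covs.current * none]
    if include_effort:
        cols.append(covs.effort)
    return np.stack(cols, axis=-1)


def effective_w_alpha(w_alpha: np.ndarray) -> np.ndarray:
    """Effective detection inclusion weights under the product rule.

    The current x none interaction contributes only when the interaction
    indicator *and* both parent indicators are 1; the intercept is always
    in.
    """
    v = np.asarray(w_alpha, dtype=float).copy()
    v[0] = 1.0
    v[3] = v[3] * v[1] * v[2]
    return v


def _effective_w_beta(w_beta: np.ndarray) -> np.ndarray:
    v = np.asarray(w_beta, dtype=float).copy()
    v[0] = 1.0
    return v


def occupancy_prob(params: DOMParams, depth=0.0, rdmv=0.0, curmax=0.0):
    """Initial-occupancy probability psi from standardized site covariates.

    ``logit(psi) = b1 + b2*depth + b3*rdmv + b4*curmax + b5*curmax^2``,
    each slope gated by its inclusion indicator.  A length-1 ``beta``
    (covariate-free submodel) returns ``inv_logit(b1)``.
    """
    depth, rdmv, curmax = (np.asarray(v, dtype=float) for v in (depth, rdmv, curmax))
    for name, v in (("depth", depth), ("rdmv", rdmv), ("curmax", curmax)):
        if np.isnan(v).any():
            raise ValueError(f"missing covariate value in {name!r}")
    if params.beta.shape[0] == 1:
        eta = np.broadcast_to(params.beta[0], np.broadcast_shapes(depth.shape, rdmv.shape, curmax.shape))
        return inv_logit(eta.astype(float))
    b = params.beta * _effective_w_beta(params.w_beta)
    eta = b[0] + b[1] * depth + b[2] * rdmv + b[3] * curmax + b[4] * curmax ** 2
    return inv_logit(eta)


def detection_prob(params: DOMParams, current, none, effort=None):
    """Per-replicate detection probability from standardized covariates.

    ``logit(p) = a1 + a2*current + a3*none + a4*current*none
    [+ a5*effort]``; each slope is gated by its (effective) inclusion
    indicator.  The effort term applies only when ``params`` carries an
    effort coefficient.
    """
    current = np.asarray(current, dtype=float)
    none = np.asarray(none, dtype=float)
    if np.isnan(current).any() or np.isnan(none).any():
        raise ValueError("missing covariate value in detection predictors")
    v = effective_w_alpha(params.w_alpha)
    a = params.alpha * v
    eta = a[0] + a[1] * current + a[2] * none + a[3] * current * none
    if params.include_effort:
        if effort is None:
            raise ValueError("missing covariate value: effort term is enabled")
        effort = np.asarray(effort, dtype=float)
        if np.isnan(effort).any():
            raise ValueError("missing covariate value in 'effort'")
        eta = eta + a[4] * effort
    return inv_logit(eta)


def _replicate_p(params: DOMParams, data: DetectionHistory, covs: CovariateSet) -> np.ndarray:
    """Detection probability per replicate slot; 0.5 filler where masked."""
    cur = np.where(data.mask, covs.current, 0.0)
    eff = np.where(data.mask, covs.effort, 0.0) if params.include_effort else None
    none = covs.none_indicator[:, None, None] * np.ones_like(cur)
    return detection_prob(params, cur, none, eff)


def _check_dims(params: DOMParams, data: DetectionHistory, covs: CovariateSet) -> None:
    if covs.n_sites != data.n_sites or covs.current.shape != data.y.shape:
        raise ValueError("detection history and covariates have mismatched dimensions")
    if params.phi.shape[0] != data.n_seasons - 1 and data.n_seasons > 1:
        raise ValueError("phi/gamma length must be n_seasons - 1")


def _log_bern(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Elementwise log Bernoulli(x | p), -inf where impossible."""
    with np.errstate(divide="ignore"):
        return np.where(x == 1, np.log(p), np.log1p(-p))


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def complete_data_loglik(params: DOMParams, z, data: DetectionHistory,
                         covs: CovariateSet) -> float:
    """Joint log-likelihood of latent states and observations.

    Sums log Bernoulli terms over initial occupancy, season-to-season
    transitions, and observed replicates; masked replicate slots are
    skipped.  Returns -inf when ``z`` contradicts a detection.
    """
    _check_dims(params, data, covs)
    _require_standardized(covs)
    if isinstance(z, LatentStates):
        z = z.z
    z = np.asarray(z, dtype=np.int8)
    if z.shape != (data.n_sites, data.n_seasons):
        raise ValueError("z must be (n_sites, n_seasons)")

    psi = occupancy_prob(params, covs.depth, covs.rdmv, covs.curmax)
    total = _log_bern(z[:, 0], np.broadcast_to(psi, (data.n_sites,))).sum()
    if data.n_seasons > 1:
        pr_next = z[:, :-1] * params.phi + (1 - z[:, :-1]) * params.gamma
        total += _log_bern(z[:, 1:], pr_next).sum()

    p = _replicate_p(params, data, covs)
    p_eff = z[:, :, None] * p
    obs_terms = _log_bern(data.y, p_eff)
    total += obs_terms[data.mask].sum()
    return float(total)


def _site_emissions(params: DOMParams, data: DetectionHistory,
                    covs: CovariateSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-(site, season) log P(replicate record | z) for z=1 and z=0."""
    p = _replicate_p(params, data, covs)
    terms = np.where(data.mask, _log_bern(data.y, p), 0.0)
    em1 = terms.sum(axis=2)
    em0 = np.where(data.has_detection, -np.inf, 0.0)
    return em1, em0


def marginal_loglik(params: DOMParams, data: DetectionHistory,
                    covs: CovariateSet) -> float:
    """Observed-data log-likelihood, latent states marginalized out.

    Sites are independent, so a per-site forward recursion over the
    two-state occupancy chain computes the sum over all ``z``
    configurations exactly; accumulation stays in log space.
    """
    _check_dims(params, data, covs)
    _require_standardized(covs)
    em1, em0 = _site_emissions(params, data, covs)
    psi = np.broadcast_to(occupancy_prob(params, covs.depth, covs.rdmv, covs.curmax),
                          (data.n_sites,))
    with np.errstate(divide="ignore"):
        l1 = np.log(psi) + em1[:, 0]
        l0 = np.log1p(-psi) + em0[:, 0]
        for t in range(1, data.n_seasons):
            phi_t, gam_t = params.phi[t - 1], params.gamma[t - 1]
            n1 = np.logaddexp(l1 + np.log(phi_t), l0 + np.log(gam_t)) + em1[:, t]
            n0 = np.logaddexp(l1 + np.log1p(-phi_t), l0 + np.log1p(-gam_t)) + em0[:, t]
            l1, l0 = n1, n0
    return float(np.logaddexp(l1, l0).sum())


def brute_force_loglik(params: DOMParams, data: DetectionHistory,
                       covs: CovariateSet) -> float:
    """Oracle log-likelihood by enumerating every latent configuration.

    Sums ``exp(complete_data_loglik)`` over all ``2^(n_sites*n_seasons)``
    occupancy configurations; only feasible for tiny designs.
    """
    n_cells = data.n_sites * data.n_seasons
    if n_cells > _BRUTE_FORCE_MAX_CELLS:
        raise ValueError(
            f"enumeration bound exceeded: {n_cells} cells > {_BRUTE_FORCE_MAX_CELLS}")
    logs = np.empty(2 ** n_cells)
    for idx, bits in enumerate(itertools.product((0, 1), repeat=n_cells)):
        z = np.asarray(bits, dtype=np.int8).reshape(data.n_sites, data.n_seasons)
        logs[idx] = complete_data_loglik(params, z, data, covs)
    finite = logs[np.isfinite(logs)]
    if finite.size == 0:
        return -np.inf
    m = finite.max()
    return float(m + np.log(np.exp(finite - m).sum()))


def recursive_occupancy(psi1, phi, gamma) -> np.ndarray:
    """Season-by-season occupancy probability under the dynamics.

    ``psi_{t+1} = psi_t * phi_t + (1 - psi_t) * gamma_t``.  ``psi1`` may
    be scalar or per-site; returns an array with a trailing season axis of
    length ``len(phi) + 1``.
    """
    psi1 = np.asarray(psi1, dtype=float)
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if phi.shape != gamma.shape:
        raise ValueError("phi and gamma must have equal length")
    out = np.empty(psi1.shape + (phi.shape[0] + 1,))
    out[..., 0] = psi1
    for t in range(phi.shape[0]):
        out[..., t + 1] = out[..., t] * phi[t] + (1 - out[..., t]) * gamma[t]
    return out
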