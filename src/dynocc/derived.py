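"""Reported quantities: finite-sample occupancy, turnover, surfaces.

The finite-sample occupancy estimator summarizes the posterior of the
proportion of the *actually sampled* sites occupied each season — the
mean of the latent states over sites, per draw — rather than the
population-level psi.  Because a detection forces occupancy, the
estimate can only revise the naive observed proportion upward.
Between-season turnover is reported as colonization (gamma), extinction
(1 - phi) and the growth rate lambda_t (ratio of successive occupied
proportions, computed per draw).  Detection-probability surfaces
propagate the full posterior over a current-speed/bottom-type grid
along a tidal cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws
from .model_core import apply_standardization

__all__ = [
    "OccupancySummary",
    "PredictionGrid",
    "finite_sample_occupancy",
    "turnover_summaries",
    "inclusion_summary",
    "make_prediction_grid",
    "predict_detection_surface",
    "detection_difference",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# occupancy and turnover
# ---------------------------------------------------------------------------

@dataclass
class OccupancySummary:
    """Posterior of the occupied proportion among the sampled sites.

    ``proportions`` is (n_draws_total, n_seasons); ``table`` holds the
    per-season median with 50% and 95% credible intervals alongside the
    naive observed proportion (share of sites with at least one
    detection).
    """

    proportions: np.ndarray
    table: pd.DataFrame


def finite_sample_occupancy(draws: PosteriorDraws) -> OccupancySummary:
    """Finite-sample occupancy estimate per season.

    Per draw and season the estimate is the mean of the latent states
    over the sampled sites; summaries are taken over draws.
    """
    z = draws.stacked("z").astype(float)
    props = z.mean(axis=1)  # (draws, seasons)
    observed = draws.has_detection.mean(axis=0)
    q = np.percentile(props, [2.5, 25.0, 50.0, 75.0, 97.5], axis=0)
    table = pd.DataFrame({
        "season": np.arange(1, props.shape[1] + 1),
        "mean": props.mean(axis=0),
        "median": q[2],
        "q25": q[1], "q75": q[3],
        "q2.5": q[0], "q97.5": q[4],
        "observed": observed,
    })
    return OccupancySummary(proportions=props, table=table)


def turnover_summaries(draws: PosteriorDraws) -> pd.DataFrame:
    """Colonization, extinction and growth per between-season interval.

    Extinction is the complement of persistence (1 - phi).  Growth
    ``lambda_t`` is the ratio of the finite-sample occupied proportions
    in seasons t+1 and t, computed per draw; draws with a zero
    denominator are dropped (their count is logged and reported).
    """
    if draws.n_seasons < 2:
        raise ValueError("turnover needs at least two seasons")
    gamma = draws.stacked("gamma")
    phi = draws.stacked("phi")
    props = finite_sample_occupancy(draws).proportions
    rows = []
    for t in range(draws.n_seasons - 1):
        for name, samples in (("colonization", gamma[:, t]),
                              ("extinction", 1.0 - phi[:, t])):
            q = np.percentile(samples, [2.5, 50.0, 97.5])
            rows.append({"interval": f"{t + 1}-{t + 2}", "quantity": name,
                         "mean": samples.mean(), "median": q[1],
                         "q2.5": q[0], "q97.5": q[2], "n_dropped": 0})
        denom = props[:, t]
        keep = denom > 0
        n_dropped = int((~keep).sum())
        if not keep.any():
            raise ValueError(f"growth undefined: occupied proportion is 0 in "
                             f"every draw of season {t + 1}")
        if n_dropped:
            logger.info("growth %d-%d: dropped %d draws with zero denominator",
                        t + 1, t + 2, n_dropped)
        lam = props[keep, t + 1] / denom[keep]
        q = np.percentile(lam, [2.5, 50.0, 97.5])
        rows.append({"interval": f"{t + 1}-{t + 2}", "quantity": "growth",
                     "mean": lam.mean(), "median": q[1], "q2.5": q[0],
                     "q97.5": q[2], "n_dropped": n_dropped})
    return pd.DataFrame(rows)


def inclusion_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior inclusion probability and keep/drop decision per term.

    A term is kept when its indicator's posterior mean exceeds 0.5
    (strictly); the interaction is assessed through its effective
    (product-rule) indicator.
    """
    rows = []
    wa = draws.stacked("w_alpha")
    for k, term in enumerate(draws.det_terms):
        if k == 0:
            continue
        if term == "current_none":
            mean = float(draws.effective_w_interaction().mean())
        else:
            mean = float(wa[:, k].mean())
        rows.append({"submodel": "detection", "parameter": term,
                     "inclusion_mean": mean, "keep": mean > 0.5})
    wb = draws.stacked("w_beta")
    for k, term in enumerate(draws.occ_terms):
        if k == 0:
            continue
        mean = float(wb[:, k].mean())
        rows.append({"submodel": "occupancy", "parameter": term,
                     "inclusion_mean": mean, "keep": mean > 0.5})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection surfaces
# ---------------------------------------------------------------------------

@dataclass
class PredictionGrid:
    """Cells with coordinates, depth-derived bottom type, and per-time
    current speed (raw m/s)."""

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    bottom_type: np.ndarray
    times: np.ndarray
    current: np.ndarray  # (n_cells, n_times)

    @property
    def n_cells(self) -> int:
        return self.cell_id.shape[0]


def make_prediction_grid(terrain, field, canopy_depth_limit_m: float = 40.0,
                         times=None) -> PredictionGrid:
    """Build a prediction grid from a terrain grid and a tidal field.

    Each terrain cell is matched to a tidal-field series (cyclically when
    the field has fewer series than cells); bottom type is canopy above
    the algal extinction depth, none below it.
    """
    elev = terrain.elevation
    nr, nc = elev.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    depth = elev.ravel()
    n_cells = depth.shape[0]
    if times is None:
        times = field.times
    t_idx = np.searchsorted(field.times, times)
    t_idx = np.clip(t_idx, 0, field.times.size - 1)
    src = np.arange(n_cells) % field.n_sites
    current = field.speed[np.ix_(src, t_idx)]
    bottom = np.where(depth > -canopy_depth_limit_m, "canopy", "none")
    return PredictionGrid(cell_id=np.arange(n_cells),
                          x=cols.ravel() * terrain.cellsize,
                          y=rows.ravel() * terrain.cellsize,
                          depth=depth, bottom_type=bottom,
                          times=np.asarray(times, dtype=float), current=current)


def _det_coefficients(draws: PosteriorDraws, terms: str) -> np.ndarray:
    """Per-draw effective detection coefficients (alpha gated by w)."""
    a = draws.stacked("alpha")
    w = draws.stacked("w_alpha").astype(float)
    if terms == "all":
        v = np.ones_like(w)
    elif terms == "kept":
        incl = inclusion_summary(draws)
        det = incl[incl.submodel == "detection"].set_index("parameter")["keep"]
        v = np.ones_like(w)
        for k, term in enumerate(draws.det_terms):
            if k > 0 and not bool(det.get(term, True)):
                v[:, k] = 0.0
    elif terms == "draws":
        v = w.copy()
        v[:, 0] = 1.0
        v[:, 3] = w[:, 3] * w[:, 1] * w[:, 2]
    else:
        raise ValueError("terms must be 'draws', 'kept' or 'all'")
    return a * v


def _p_draws(coef: np.ndarray, current_std: np.ndarray, none: np.ndarray,
             effort_std: float = 0.0) -> np.ndarray:
    """(n_draws, n_points) detection probabilities."""
    eta = (coef[:, 0, None]
           + coef[:, 1, None] * current_std[None, :]
           + coef[:, 2, None] * none[None, :]
           + coef[:, 3, None] * current_std[None, :] * none[None, :])
    if coef.shape[1] > 4:
        eta = eta + coef[:, 4, None] * effort_std
    return expit(eta)


def predict_detection_surface(draws: PosteriorDraws, grid: PredictionGrid,
                              times=None, terms: str = "draws",
                              use_posterior_means: bool = False,
                              effort_minutes: float | None = None) -> pd.DataFrame:
    """Posterior detection-probability surface over cells and times.

    Grid currents are standardized with the fit's stored constants (an
    error if absent).  By default the full posterior is propagated
    per cell and time (mean plus 2.5/97.5% bounds); with
    ``use_posterior_means`` only the posterior-mean coefficients are
    pushed through the link.  Effort is held at the sample mean unless
    ``effort_minutes`` is given.
    """
    consts = draws.standardization_constants
    if consts is None or "current" not in consts:
        raise ValueError("posterior draws carry no standardization constants "
                         "for 'current'")
    if times is None:
        times = grid.times
    times = np.asarray(times, dtype=float)
    t_pos = np.searchsorted(grid.times, times)
    t_pos = np.clip(t_pos, 0, grid.times.size - 1)
    coef = _det_coefficients(draws, terms)
    if use_posterior_means:
        coef = coef.mean(axis=0, keepdims=True)
    eff_std = 0.0
    if draws.include_effort and effort_minutes is not None:
        eff_std = float(apply_standardization(effort_minutes, "effort", consts))
    none = (grid.bottom_type == "none").astype(float)
    records = []
    for j, t in zip(t_pos, times):
        cur_raw = grid.current[:, j]
        cur_std = apply_standardization(cur_raw, "current", consts)
        p = _p_draws(coef, cur_std, none, eff_std)
        lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
        records.append(pd.DataFrame({
            "cell_id": grid.cell_id, "x": grid.x, "y": grid.y,
            "depth_m": grid.depth, "bottom_type": grid.bottom_type,
            "time": t, "current_ms": cur_raw,
            "p_mean": p.mean(axis=0), "p_lo": lo, "p_hi": hi,
        }))
    return pd.concat(records, ignore_index=True)


def detection_difference(draws: PosteriorDraws, currents_ms,
                         terms: str = "draws") -> pd.DataFrame:
    """Posterior of ``p_none - p_canopy`` along a current-speed range.

    Returns the per-current posterior mean and 95% band of the
    bottom-type contrast in detection probability, flagging currents
    where the band excludes zero (a credible difference).  Computed per
    draw, then summarized.
    """
    consts = draws.standardization_constants
    if consts is None or "current" not in consts:
        raise ValueError("posterior draws carry no standardization constants "
                         "for 'current'")
    currents_ms = np.asarray(currents_ms, dtype=float)
    cur_std = apply_standardization(currents_ms, "current", consts)
    coef = _det_coefficients(draws, terms)
    p_none = _p_draws(coef, cur_std, np.ones_like(cur_std))
    p_canopy = _p_draws(coef, cur_std, np.zeros_like(cur_std))
    diff = p_none - p_canopy
    lo, hi = np.percentile(diff, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "current_ms": currents_ms,
        "mean": diff.mean(axis=0),
        "q2.5": lo, "q97.5": hi,
        "excludes_zero": (lo > 0) | (hi < 0),
    })
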