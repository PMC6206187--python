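"""File formats and run configuration.

Tabular dialects (all plain CSV):

* detections — ``site_id, season, replicate, y, obs_time, effort_min,
  current_ms`` (long format; replicate-level covariates ride along with
  the binary records),
* covariates — ``site_id, depth_m, rdmv, curmax_ms, bottom_type`` keyed
  by site,
* tidal series — ``site_id, time_iso8601, speed_ms``,
* terrain — plain-text ASCII grid with an ``ncols/nrows/cellsize``
  header.

Seasons are encoded as integers 1..T; an optional sidecar label map
carries display names.  ``RunConfig`` is the single structured
configuration (model choice, priors, chains, simulation parameters,
seed); it round-trips losslessly through YAML and rejects unknown keys.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .inference import ChainConfig, PRIOR_PRESETS, PriorConfig
from .model_core import CovariateSet, DetectionHistory

__all__ = [
    "DETECTIONS_COLUMNS",
    "COVARIATES_COLUMNS",
    "write_detections_csv",
    "read_detections_csv",
    "write_covariates_csv",
    "read_covariates_csv",
    "load_dataset",
    "write_tidal_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "PriorSpec",
    "ChainSpec",
    "SimSpec",
    "RunConfig",
    "run_manifest",
]

DETECTIONS_COLUMNS = ["site_id", "season", "replicate", "y", "obs_time",
                      "effort_min", "current_ms"]
COVARIATES_COLUMNS = ["site_id", "depth_m", "rdmv", "curmax_ms", "bottom_type"]

TIDAL_EPOCH = pd.Timestamp("2006-06-01T00:00:00")


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def write_detections_csv(history: DetectionHistory, covs: CovariateSet,
                         path) -> None:
    """Write the long-format detection table (one row per observed
    replicate) with its replicate-level covariates (raw units)."""
    sites, seasons, reps = np.nonzero(history.mask)
    obs_time = (history.obs_time[history.mask] if history.obs_time is not None
                else np.full(sites.shape[0], np.nan))
    pd.DataFrame({
        "site_id": sites + 1,
        "season": seasons + 1,
        "replicate": reps + 1,
        "y": history.y[history.mask],
        "obs_time": obs_time,
        "effort_min": covs.effort[history.mask],
        "current_ms": covs.current[history.mask],
    }).to_csv(path, index=False)


def read_detections_csv(path):
    """Read the detection table.

    Returns ``(DetectionHistory, replicate_covariates)`` where the dict
    holds the ``current`` and ``effort`` arrays aligned with the history.
    Malformed rows (y outside {0, 1}, duplicated keys) raise with their
    line numbers; replicate gaps simply leave mask entries off.
    """
    df = pd.read_csv(path)
    missing = [c for c in DETECTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detections file missing columns: {missing}")
    bad = ~df["y"].isin((0, 1))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"y outside {{0,1}} at line(s) {lines}")
    dup = df.duplicated(subset=["site_id", "season", "replicate"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (site_id, season, replicate) at line(s) {lines}")
    site_ids = np.sort(df["site_id"].unique())
    site_pos = {s: i for i, s in enumerate(site_ids)}
    n_sites = site_ids.size
    n_seasons = int(df["season"].max())
    max_reps = int(df["replicate"].max())
    shape = (n_sites, n_seasons, max_reps)
    y = np.zeros(shape, dtype=np.int8)
    mask = np.zeros(shape, dtype=bool)
    obs_time = np.full(shape, np.nan)
    current = np.full(shape, np.nan)
    effort = np.full(shape, np.nan)
    i = df["site_id"].map(site_pos).to_numpy()
    t = df["season"].to_numpy(int) - 1
    j = df["replicate"].to_numpy(int) - 1
    y[i, t, j] = df["y"].to_numpy(int)
    mask[i, t, j] = True
    obs_time[i, t, j] = df["obs_time"].to_numpy(float)
    current[i, t, j] = df["current_ms"].to_numpy(float)
    effort[i, t, j] = df["effort_min"].to_numpy(float)
    history = DetectionHistory(y=y, mask=mask, obs_time=obs_time)
    return history, {"current": current, "effort": effort,
                     "site_ids": site_ids}


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def write_covariates_csv(covs: CovariateSet, path) -> None:
    pd.DataFrame({
        "site_id": np.arange(1, covs.n_sites + 1),
        "depth_m": covs.depth,
        "rdmv": covs.rdmv,
        "curmax_ms": covs.curmax,
        "bottom_type": covs.bottom_type,
    }).to_csv(path, index=False)


def read_covariates_csv(path, replicate_covariates: dict | None = None) -> CovariateSet:
    """Read site covariates; replicate-level current/effort come from the
    detections file (pass the dict from :func:`read_detections_csv`) or
    default to NaN placeholders."""
    df = pd.read_csv(path)
    missing = [c for c in COVARIATES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariates file missing columns: {missing}")
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in covariates file")
    df = df.sort_values("site_id").reset_index(drop=True)
    n = len(df)
    if replicate_covariates is not None:
        current = replicate_covariates["current"]
        effort = replicate_covariates["effort"]
        if current.shape[0] != n:
            raise ValueError("covariates and detections disagree on the "
                             "number of sites")
    else:
        current = np.full((n, 1, 1), np.nan)
        effort = np.full((n, 1, 1), np.nan)
    return CovariateSet(depth=df["depth_m"].to_numpy(float),
                        rdmv=df["rdmv"].to_numpy(float),
                        curmax=df["curmax_ms"].to_numpy(float),
                        bottom_type=df["bottom_type"].to_numpy(str),
                        current=current, effort=effort)


def load_dataset(detections_path, covariates_path):
    """Read both files into aligned ``(DetectionHistory, CovariateSet)``."""
    history, rep_covs = read_detections_csv(detections_path)
    covs = read_covariates_csv(covariates_path, rep_covs)
    return history, covs


# ---------------------------------------------------------------------------
# tidal series and terrain
# ---------------------------------------------------------------------------

def write_tidal_csv(field, path) -> None:
    n_sites, n_times = field.speed.shape
    stamps = TIDAL_EPOCH + pd.to_timedelta(field.times, unit="s")
    pd.DataFrame({
        "site_id": np.repeat(np.arange(1, n_sites + 1), n_times),
        "time_iso8601": np.tile(stamps.strftime("%Y-%m-%dT%H:%M:%S"), n_sites),
        "speed_ms": field.speed.ravel(),
    }).to_csv(path, index=False)


def write_ascii_grid(grid, path) -> None:
    """Plain-text ASCII grid (ncols/nrows/cellsize header)."""
    elev = grid.elevation
    header = (f"ncols {elev.shape[1]}\nnrows {elev.shape[0]}\n"
              f"cellsize {grid.cellsize}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, elev, fmt="%.4f")


def read_ascii_grid(path):
    from .synthetic_data import TerrainGrid
    with open(path) as fh:
        meta = {}
        for _ in range(3):
            key, val = fh.readline().split()
            meta[key] = float(val)
        elev = np.loadtxt(fh)
    elev = elev.reshape(int(meta["nrows"]), int(meta["ncols"]))
    return TerrainGrid(elevation=elev, cellsize=meta["cellsize"])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class PriorSpec(BaseModel):
    """Coefficient-prior choice: a named preset or custom t parameters."""

    model_config = ConfigDict(extra="forbid")

    name: Literal["dorazio", "firth_t", "gelman", "custom"] = "dorazio"
    mu: Optional[float] = None
    sigma: Optional[float] = Field(default=None, gt=0)
    nu: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _custom_needs_params(self):
        if self.name == "custom" and (self.sigma is None or self.nu is None):
            raise ValueError("custom prior requires sigma and nu")
        return self

    def to_prior(self) -> PriorConfig:
        base = PRIOR_PRESETS.get(self.name, PRIOR_PRESETS["dorazio"])
        return PriorConfig(
            mu=self.mu if self.mu is not None else base.mu,
            sigma=self.sigma if self.sigma is not None else base.sigma,
            nu=self.nu if self.nu is not None else base.nu,
            name=self.name)


class ChainSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_chains: int = Field(default=5, ge=1)
    n_draws: int = Field(default=50_000, ge=2)
    burn_in: int = Field(default=10_000, ge=0)
    thin: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _burn_lt_draws(self):
        if self.burn_in >= self.n_draws:
            raise ValueError("burn_in must be smaller than n_draws")
        return self

    def to_chains(self, seed: int) -> ChainConfig:
        return ChainConfig(n_chains=self.n_chains, n_draws=self.n_draws,
                           burn_in=self.burn_in, thin=self.thin, seed=seed)


class SimSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_sites: int = Field(default=14, ge=1)
    n_seasons: int = Field(default=4, ge=1)
    season_days: float = Field(default=7.0, gt=0)
    period_hr: float = Field(default=12.42, gt=0)
    step_min: float = Field(default=20.0, gt=0)
    max_lag_hr: float = Field(default=1.0, ge=0)
    amplitude_min: float = Field(default=0.15, gt=0)
    amplitude_max: float = Field(default=0.30, gt=0)
    noise_sd: float = Field(default=0.005, ge=0)
    canopy_depth_limit_m: float = Field(default=40.0, gt=0)
    reps_dist: tuple[float, float, float] = (0.25, 0.5, 0.25)
    effort_min: float = Field(default=30.0, gt=0)
    effort_max: float = Field(default=90.0, gt=0)


class RunConfig(BaseModel):
    """One reproducible run: model choice, priors, chains, simulation."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["A", "B"] = "A"
    include_effort: bool = True
    prior: PriorSpec = PriorSpec()
    chains: ChainSpec = ChainSpec()
    sim: SimSpec = SimSpec()
    seed: int = Field(default=0, ge=0)
    verbosity: str = "INFO"

    _STAGES = {"simulate": 1, "fit": 2, "diagnose": 3, "predict": 4,
               "sensitivity": 5}

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        idx = self._STAGES.get(stage)
        if idx is None:
            raise ValueError(f"unknown stage {stage!r}")
        state = np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
        return int(state % (2 ** 31))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_manifest(config: RunConfig, stage: str, artifacts: list[str]) -> dict:
    import dynocc
    return {
        "stage": stage,
        "config_sha256": config.digest(),
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "stage_seed": config.child_seed(stage),
        "artifacts": artifacts,
        "versions": {"dynocc": dynocc.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
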