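# Methods

## Model

`dynocc` implements the Bayesian dynamic (multi-season) site-occupancy
model in the Royle–Kéry parameterization. For sites `i = 1..N`, seasons
`t = 1..T` and replicate surveys `j` within a season:

- `z[i, 1] ~ Bernoulli(psi_i)` — initial occupancy;
- `z[i, t+1] ~ Bernoulli(z[i, t]·phi_t + (1 − z[i, t])·gamma_t)` —
  persistence `phi_t` and colonization `gamma_t`, constant across sites
  within each between-season interval;
- `y[i, t, j] ~ Bernoulli(z[i, t]·p[i, t, j])` — imperfect detection.

Assumptions: closure within a season (occupancy changes only between
seasons), independence between sites (no spatial autocorrelation), and at
least one site-season with more than one replicate so that detection and
occupancy are separable. Extinction is reported as the complement of
persistence, `1 − phi_t`.

Initial occupancy (model B) is a logit-linear function of standardized
depth, RDMV (relative deviation from the mean value, a 3×3-window terrain
attribute in [−1, 1]), seasonal maximum current, and its square; model A
is intercept-only. Detection is logit-linear in the standardized current
speed at the moment of observation, a canopy-absent bottom-type indicator
(`none`), their interaction, and — optionally but by default — sampling
effort (bottom time in minutes). The printed detection equation of the
source analysis omits effort while its fitted-coefficient table includes
it; the effort term is therefore a config switch, enabled by default to
match the fitted model.

Numerical conventions, chosen where the original analysis is silent:

- standardization uses the sample SD (`n − 1` denominator), computed over
  sites for site-level covariates and over all observed replicate records
  for replicate-level ones; the constants are stored with the fit and
  reused for prediction;
- the quadratic occupancy term is the square of the *standardized*
  maximum current (standardize-then-square), so it is centered;
- depth is negative metres below datum;
- missing replicates are handled by a mask; masked cells contribute no
  likelihood terms;
- RDMV edge cells use the truncated window (no padding), and a flat
  window (zero range) maps to 0.

## Likelihoods

Three likelihood paths coexist deliberately. The complete-data
log-likelihood scores a parameter state jointly with a latent-state
configuration (−inf when `z` contradicts a detection). The marginal
log-likelihood integrates `z` out exactly by a per-site forward recursion
over the two-state chain, accumulated in log space. A brute-force oracle
enumerates all `2^(N·T)` configurations (bounded at 16 cells) and exists
only to validate the recursion; the test suite checks agreement to 1e−8
across random designs and that the probability model sums to one over all
possible detection histories.

## Sampler

Inference is Metropolis-within-Gibbs with explicit data augmentation —
the sampler itself is the point of the package rather than delegation to
a generic MCMC engine. Each sweep:

1. draws `z` for all sites jointly by forward filtering / backward
   sampling (an exact conditional draw, vectorized over sites; cells with
   a detection are occupied with probability 1);
2. updates `phi_t`, `gamma_t` from their exact conjugate conditionals,
   `Beta(1 + successes, 1 + failures)` of the latent transition counts
   (uniform priors);
3. updates each coefficient by scalar random-walk Metropolis against the
   complete-data likelihood given `z` (detection coefficients touch only
   observations at occupied site-seasons);
4. Gibbs-updates each inclusion indicator from its conditional odds —
   the likelihood ratio with the term in versus out times prior odds 1.

Indicator selection follows the Kuo–Mallick scheme with the prior as
pseudo-prior: while a term is excluded its coefficient is resampled
directly from the prior, so no reversible-jump machinery is needed and an
empty likelihood reproduces the prior exactly. The interaction's
effective indicator is the product `w_int·w_current·w_none`, so it
contributes only when both main effects are in; its reported inclusion
probability is the mean of that product.

Coefficients take weakly informative scaled-t priors, default
`mu = 0, sigma = 1.566, nu = 7.763`. Proposal scales start at 0.4 and
adapt every 100 iterations during burn-in only (shrunk below 20%
acceptance, grown above 50%), then freeze to preserve detailed balance.
Chains start over-dispersed: coefficients from twice the prior scale,
`phi`/`gamma` uniform, `z` set to 1 wherever detected and Bernoulli(0.5)
elsewhere. Default chain settings are 5 chains × 50,000 draws with
10,000 burn-in and thinning by 10; every run in the test suite and the
acceptance script uses the scaled desk configuration 4 × 4,000 (burn-in
1,000, thin 10), which the convergence diagnostics accept comfortably on
the simulated designs. One global seed fans out to per-stage child seeds
through `numpy.random.SeedSequence`, so stages rerun independently and
reproducibly.

## Validation suite

- **Convergence** — the classic Gelman–Rubin PSRF `sqrt(V̂/W)` per
  parameter and the Brooks–Gelman multivariate statistic over the
  coefficient block; values below 1.1 count as converged. The classic
  formula (not the rank-normalized variant) is used so the statistic has
  a closed hand-checkable form.
- **Goodness of fit** — a posterior-predictive Bayesian p-value: for
  each stored draw a replicate dataset is simulated conditional on that
  draw's latent states, and summed squared Pearson residuals
  `r = (y − z·p)/sqrt(z·p(1 − z·p) + 1e−6)` are compared between
  observed and simulated data. The replication conditions on the drawn
  `z` (observation-level residuals, the standard occupancy GOF
  construction) rather than regenerating `z` per draw; both readings are
  defensible and the conditional one is implemented.
- **Identifiability** — percent overlap between the prior density and a
  Gaussian-KDE posterior estimate (Silverman bandwidth, trapezoid
  integration on a 1,024-point grid spanning both densities' 0.0001
  quantiles); below 35% counts as identifiable.
- **Prior sensitivity** — refits under three recommended logistic
  priors: t(0, 1.566, 7.763), t(0, 2.5, 7) (the scaled-t approximation of
  the Jeffreys/Firth prior — no data-dependent Jeffreys prior is
  computed), and t(0, 2.5, 1).

## Derived quantities

The finite-sample occupancy estimate is, per draw and season, the mean of
`z` over the sampled sites — appropriate for a small, non-random site
sample. It is reported as the posterior median with 50% and 95% credible
intervals next to the naive observed proportion, and dominates the
observed proportion in every draw by construction. Growth
`lambda_t` is the ratio of occupied proportions in successive seasons
computed *per draw* and then summarized (the ratio of posterior means
differs by a Jensen gap; the tests pin this distinction); draws with a
zero denominator are dropped and counted. Detection surfaces propagate
the full posterior (optionally only the posterior-mean coefficients, or
only the kept terms) over a current-speed/bottom-type grid along a tidal
cycle; the bottom-type contrast `p_none − p_canopy` is summarized with a
95% band and flagged where the band excludes zero.

## Synthetic data

The generator emulates the study design, not the physics:

- **Tidal field** — per site, a rectified single-constituent sinusoid
  `|A_i sin(2π(t − lag_i)/T)| + floor`, period 12.42 h (M2), 20-minute
  step, amplitudes uniform in 0.15–0.30 m/s, floor 0.01 m/s, speeds
  clipped to 0.31 m/s, phase lags spread evenly over 0–1 h, optional
  small Gaussian noise. It reproduces the printed range, period and
  inter-site lag of the modelled bottom currents and nothing else — no
  wave-current physics, no harmonic structure beyond one constituent,
  and no dependence of flow on local topography.
- **Sites** — 14 sites by default in 2/6/6 depth strata with
  per-stratum covariate envelopes mirroring the study's summary table;
  bottom type is canopy above the 40 m algal extinction depth.
  Site covariates are drawn independently of the tidal amplitudes.
- **Surveys** — four seasons as abutting equal blocks of the tidal
  series (one week per season by default; the real calendar is not
  modelled), replicate counts per site-season drawn from
  (0.25, 0.5, 0.25) over {1, 2, 3} (mean two), observation times uniform
  within the season window (mirroring a time randomly sampled from the
  video for null observations), currents matched to the nearest tidal
  step (ties to the earlier step), effort uniform in 30–90 minutes.
- **Default truth** — detection coefficients at the fitted model-A
  posterior means (−1.57, −1.26, 3.01, 1.77; effort −0.37), initial
  occupancy 0.8, persistence (0.44, 0.56, 0.85) and colonization
  (0.52, 0.77, 0.55) matching the reported turnover.
- **Recovery benchmark** — 200 sites, three replicates everywhere,
  detection coefficients (−1.5, −1.2, 3.0, 1.8) with no effort effect
  (so a fitted effort term is a known null), initial occupancy 0.6,
  `phi = 0.7`, `gamma = 0.4`: enough occupied site-seasons to identify
  the detection submodel while keeping a desk-scale runtime.

Because the generator samples from exactly the model the sampler fits,
passing recovery and calibration tests demonstrates internal correctness
of likelihoods, sampler and summaries — not robustness to the
misspecification, spatial dependence, or observation artefacts of real
survey data.

## Known limitations

- No maximum-likelihood path, no reversible-jump or Hamiltonian
  sampling, and no model classes beyond A and B.
- No WAIC/LOO/DIC comparison; model assessment is GOF, identifiability
  and sensitivity only.
- Currents are not interpolated between cells and maps are plain tables;
  rendering is left to the caller.
- Scalar Metropolis updates mix slowly under strong posterior
  correlation; the adaptive scales and the exact `z`, `phi`, `gamma`
  and `w` conditionals keep the desk-scale settings adequate on the
  simulated designs, as the convergence checks verify per run.
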