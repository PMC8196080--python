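# Methods

## The model

### Stock and flow

For each country and net type (long-lasting nets, `llin`; conventional
treated nets, `citn`) the model runs on a quarterly grid. Observable inputs
are quarterly manufacturer deliveries, annual reported distribution counts,
an annual population-at-risk series, and a handful of survey-based national
net-crop estimates with standard errors. Latent quantities are the true
quarterly distributions and the loss-curve parameters.

Two structural rules define the model:

* **Bounds.** In every year, true distributed nets lie between the reported
  count (reports miss distributions but do not invent them) and the
  available stock (carry-over plus deliveries). The sampler parameterises
  the annual total as `reported + u · (ceiling − reported)` with
  `u ∈ [0, 1]`; the ceiling subtracts a backward-computed *reserve* — the
  stock that must be carried forward for future reported floors to stay
  reachable — so every draw satisfies both bounds for any `u` path, given
  globally feasible inputs (cumulative reports ≤ cumulative deliveries,
  checked up front).
* **Attrition.** Cohorts decay along the compact-support curve
  `f(t) = exp(k − k/(1 − (t/L)²))`, `f ≡ 0` beyond `L`. Crop is the
  convolution of quarterly distributions with `f`. Steepness `k` is fixed
  at 20 by default (an option exposes it): with sparse surveys only one
  retention degree of freedom is identifiable, and fixing `k` makes the
  median retention τ a bijection of `L`
  (τ = L·√(ln 2/(k + ln 2))).

Within a year, the annual total is split over quarters proportionally to an
estimated seasonal simplex (softmax of three scores, standard-normal prior)
multiplied by each quarter's stock inflow. The inflow factor encodes that
nets are mostly handed out soon after they arrive — which is how mass
campaigns operate — and lets the quarterly delivery series carry campaign
timing into the likelihood; the seasonal simplex lets data move the split
away from pure inflow proportionality. The conventional-net channel has no
separate delivery ledger, so its reported distributions are taken as
deliveries (delivery = distribution) and only its retention parameter is
sampled.

Priors: τ ~ U[1, 6] years per net type (the lower bound mirrors the fitting
floor used in practice; the upper bound is ours — no country estimate
approaches it), u ~ U[0, 1] per year. Both are sampled through sigmoid
scores with standard-logistic priors, which keeps the implied priors
exactly uniform while giving the ensemble sampler an unbounded space.
Likelihood: survey crop estimate ~ Normal(model crop at the survey quarter,
SE), with SE floored at 1% of the estimate to avoid degenerate precision
from implausibly tight surveys.

Sampling uses the `emcee` ensemble sampler with differential-evolution
moves (80% DE, 20% snooker), which mix far better than stretch moves in
this ~25-dimensional, partially flat posterior. Defaults: 64 walkers (or
2·dim+2 if larger), 4000 steps, 2000 discarded, thinned by 20. Convergence
is monitored by a split Gelman–Rubin statistic over walkers on the
retention parameters; values above 1.05 emit a warning (walkers of one
ensemble are not independent chains, so this diagnostic is conservative —
values of ~1.05–1.10 at the default budget are typical and benign for the
summaries reported). A fit with no surveys runs on the priors alone and is
flagged `low_confidence`.

### Coverage metrics

All indicators use the de facto household population as denominator.
Individual-level access counts `min(2 · nets, size)` people per household;
household-level access uses the exact ratio test `nets ≥ size/2` with no
rounding. Use is the proportion who slept under a net; the use rate is
use/access and is NaN-flagged (not an error) where access is zero. Use may
exceed access where more than two people share a net.

Crop-to-access conversion fits a monotone saturating calibration curve
`access = g(npc)` — isotonic regression anchored at g(0)=0 and capped at 1,
smoothed by a monotone PCHIP spline through the isotonic knots — to
calibration pairs of (NPC, access). In the pipeline those pairs come from
the survey cluster aggregates themselves; in tests, from the allocation
oracle. Evaluations outside the calibrated NPC range are clamped and
flagged.

Deviation metrics per cluster-month: access deviation = local − national
access; NPC deviation likewise; the additive signed use gap
`use − access` is stored so the composition `use = access + gap` is exactly
additive, while the reported `use_gap` column carries the conventional sign
(access − use, positive = under-use). Both conventions coexist in the
output because the field uses both; the signed field is the one composition
consumes.

### Geostatistical stage

Each deviation metric is transformed — empirical logit
`ln((x+1+ε)/(1−x+ε))` first for the [−1, 1] metrics, then inverse
hyperbolic sine for all — and modelled as linear fixed effects (intercept +
covariate value) plus a zero-mean Gaussian process with separable
covariance `σ² · Matérn₃/₂(d/ρ) · φ^|Δt|` and an iid nugget. Transform
order (domain map first, asinh second) is inverted in reverse after
prediction. ε defaults to 1e-3 throughout the pipeline; a per-aggregate
`1/(2·n_eff)` helper (floored at 1e-3) is available where observation-level
ε is preferred. Smoothness is fixed at ν = 3/2: typical for coverage
surfaces, and not identifiable from a few hundred points.

Hyperparameters (σ², ρ, nugget on log scale, φ through tanh) maximise the
Gaussian marginal likelihood with the fixed effects profiled out by GLS;
optimisation is Nelder–Mead from data-driven starts. Everything is an
exact dense solve — Cholesky with escalating diagonal jitter, hard failure
if the covariance stays indefinite — which is feasible to a few thousand
observations and is the reference that sparse/mesh approximations target.
Distances are planar grid units; great-circle geometry is irrelevant at
this scale. Time is calendar months. Prediction returns the posterior mean
and joint draws on the grid (fixed effects at their GLS estimates, i.e.
their uncertainty is not propagated; the dominant uncertainty at desk scale
is the field and nugget).

Maps are composed per draw: access = clamp(national + deviation, 0, 1),
use = clamp(access + signed gap, 0, 1), NPC = max(national + deviation, 0),
use rate = use/access. Clamping is our choice — out-of-domain sums have no
defined handling otherwise — and is applied after the additive identity is
formed, so the identity holds exactly pre-clamp. National draws and
deviation draws are combined independently, which widens the composed
intervals slightly relative to a joint model; the two stages share no
parameters, so no correlation information exists to exploit.

Relative gain: per cell, the use gained if the use rate were 100% at
current access (`access − use`) versus if access were 100% at the current
use rate (`use/access − use`, rate capped at 1). Whenever the use rate
exceeds access, the access counterfactual dominates algebraically — the
mechanism behind "improve access first" conclusions.

Uncertainty displays: bivariate classification assigns each cell a
(mean-quantile-bin, CI-width-quantile-bin) pair using population-weighted
quantile bins (default 4×4); exceedance maps give the fraction of draws
above a threshold per cell.

## Synthetic-data generator

The generator defines the study conditions and is first-class, tested
code. Per country it simulates 2000–2020 (84 quarters) on a 30×30 abstract
grid (row-major, cell = one distance unit, pixel (0,0) at the north-west
corner) standing in for 5-km pixels:

* **Deliveries**: mass campaigns every 3 years procuring one net per 1.8
  people at risk (0.56 NPC, the standard planning quantity), landing 60/40
  in the first two quarters of the campaign year, plus a continuous routine
  channel (0.03 nets/person-year). A small conventional-net channel (0.01
  nets/person-year) runs in the first six years.
* **Distributions**: each quarter empties a fixed fraction of available
  stock (85% in campaign quarters, 35% otherwise), so cumulative
  distributions never exceed cumulative deliveries by construction.
  Reports capture 90% of true distributions (rounded); the conventional
  channel is reported fully (its ledger *is* the report).
* **Attrition**: LLIN median retention 2.0 years, conventional 1.5 years,
  steepness 20. True crop is exactly the distribution-loss convolution.
* **Allocation**: nets are assigned one at a time; with probability 1−m to
  the household with greatest unmet need (ceil(size/2) − nets), otherwise
  to a uniformly random household capped at one net per person. m = 0 gives
  access = min(1, 2·NPC) exactly on even household sizes (the analytic
  oracle); the default m = 0.5 produces the observed plateau of access
  against NPC. The mechanism itself is invented — what is documented in
  the field is its consequence, the saturation — and m is the single dial
  controlling it.
* **Surfaces**: NPC deviation and use-propensity fields are unit-variance
  Matérn-3/2 draws (range 8 grid units) evolving as stationary AR1 across
  quarters (φ = 0.85), each loaded 0.5 on a shared covariate raster and
  restandardised. Pixel NPC = max(0, national + 0.08·field); pixel access
  comes from the Monte-Carlo allocation curve at the pixel's NPC; pixel use
  = p(use)·(access + sharing slack), with p(use) a logistic in a seasonal
  sinusoid (base 1.6, amplitude 0.6 — use is high among those with access,
  with visible seasonality) plus the pixel propensity offset. Population is
  a lognormal-type transform of a field draw (mean 500 persons/pixel); the
  population-at-risk mask drops the bottom 5% of cells.
* **Surveys**: 50 clusters sampled probability-proportional-to-population,
  20 households each, sizes from a categorical PMF on 1..15 (mean ≈ 4.8,
  mode 4, the shape of regional survey data). Cluster nets ~
  Poisson(NPC·population) capped at capacity, allocated with the configured
  m; sleepers are Binomial(covered, p_use) plus occasional third sleepers
  (probability 0.05 per net with slack), which lets use exceed access
  locally. Household sizes are capped at 15 and drawn from an explicit PMF
  for exact control.

What the generator does *not* emulate: demography and migration, net
fishing/repurposing, insecticide decay, private-sector nets, survey
non-response and weighting artefacts, country borders in the covariance
structure. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions plus controlled
misspecification (under-reporting, allocation saturation, seasonal use) —
not robustness to everything real surveys do.

## Numerical choices

* Quarter length 0.25 years everywhere; a survey month maps to its
  enclosing quarter.
* Loss-curve evaluation is exact at the endpoints (1 at 0, 0 at and beyond
  L) rather than relying on floating-point limits.
* Cholesky jitter escalates multiplicatively from 10⁻¹⁰ of the mean
  diagonal before failing.
* The GP duplicate-point check rounds coordinates to 9 decimals; the
  pipeline adds 10⁻⁶ jitter because two clusters can share a pixel-month.
* Survey SEs are cluster-robust (variance of cluster means); a single
  cluster falls back to the household-level SE.
* Ties in the greedy allocator break toward the lowest household index;
  reproducibility is guaranteed by seeding every generator explicitly
  (string hashes are avoided in seed derivation).
* Stage seeds derive from the master seed as
  `(master·10007 + crc32(stage)) mod 2³¹`.

## Problem sizes

Defaults were chosen so a full pipeline run (two countries, 21 years,
30×30 grid, four surveys per country, 100 posterior draws per surface)
completes in a few minutes on one core: the MCMC dominates (~1–2 minutes
per country), the dense GP stage is seconds. The parameter-recovery suite
uses one country and the same horizon. Larger grids and observation counts
scale as O(n³) in the GP and linearly in the sampler.

## Known limitations

* The within-year distribution profile is shared across years (modulated by
  stock inflow); a country whose campaign season drifts over time would be
  mis-timed.
* Fixed-effect uncertainty is not propagated into prediction draws.
* The national and pixel stages are composed independently per draw.
* With a single survey the retention posterior is honest but wide, and the
  crop trajectory between surveys is prior-dominated within the
  report/stock envelope.
* The crop-to-access calibration is only as good as the coverage of its
  calibration pairs; extrapolation is clamped and flagged, not modelled.
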