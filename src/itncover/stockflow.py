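"""National quarterly stock-and-flow model of net distribution and loss.

The mechanistic model tracks, for one country and per net type (LLIN and
conventional ITN), the chain

    manufacturer deliveries -> national stock -> distribution to households
    -> net crop (nets in homes), decaying along a compact-support loss curve.

Two rules constrain the unobserved true distributions:

1. nets distributed in a year are bounded below by the reported distribution
   count and above by the available stock (carry-over plus deliveries);
2. net loss follows the smooth compact retention curve, with a separate
   median retention time per net type estimated from household-survey
   net-crop estimates.

Inference is Bayesian: an affine-invariant ensemble sampler (emcee) explores
median retention times tau (uniform prior on [1, 6] years, steepness k fixed
at 20 by default), per-year distribution fractions u in [0, 1] interpolating
between the reported floor and the stock ceiling, and a shared within-year
quarterly allocation simplex. The likelihood is Gaussian on the crop scale:
survey estimate ~ N(model crop at the survey quarter, SE), with SEs floored
at 1% of the estimate. Every retained draw satisfies the stock and reporting
bounds by construction.

Conventional ITNs have no delivery ledger of their own: reported
distributions are taken as deliveries (delivery = distribution), so only
their retention parameter is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import emcee

from .loss import LossCurve, curve_from_retention, quarterly_crop, QUARTER_YEARS

__all__ = [
    "CountryInputs", "StockFlowPosterior", "survey_crop_estimate",
    "fit_stock_and_flow", "MCMCSettings",
]

TAU_PRIOR = (1.0, 6.0)  # years; lower bound mirrors the fitting floor


@dataclass
class CountryInputs:
    """Inputs for one country.

    Attributes
    ----------
    deliveries : dict mapping net type ("llin") to quarterly delivery counts.
    reported : dict mapping net type to *annual* reported distribution counts
        ("citn" entries are treated as deliveries too: delivery=distribution).
    population : annual population-at-risk series (persons).
    surveys : list of (quarter_index, crop_estimate, se) tuples.
    """

    deliveries: dict
    reported: dict
    population: np.ndarray
    surveys: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        for d in (self.deliveries, self.reported):
            for k, v in d.items():
                arr = np.asarray(v, dtype=float)
                if np.any(arr < 0):
                    raise ValueError(f"negative counts in {k}")
                d[k] = arr
        for q, est, se in self.surveys:
            if se <= 0:
                raise ValueError("survey SE must be > 0")

    @property
    def n_years(self) -> int:
        return len(self.population)

    @property
    def n_quarters(self) -> int:
        return 4 * self.n_years


@dataclass
class MCMCSettings:
    n_walkers: int = 64
    n_steps: int = 4000
    n_burn: int = 2000
    thin: int = 20
    seed: int = 0


@dataclass
class StockFlowPosterior:
    """Retained posterior draws and quarterly summaries."""

    tau: dict                 # net type -> (n_draws,) median retention, years
    distributed: dict         # net type -> (n_draws, n_quarters)
    crop: np.ndarray          # total crop, (n_draws, n_quarters)
    crop_by_type: dict
    npc: np.ndarray           # (n_draws, n_quarters)
    summary: pd.DataFrame     # per-quarter mean / 2.5% / 97.5%
    rhat: dict
    low_confidence: bool
    converged: bool

    def constraint_audit(self, inputs: CountryInputs) -> bool:
        """True iff every draw satisfies the annual report/stock bounds."""
        for t, dist in self.distributed.items():
            annual = dist.reshape(dist.shape[0], -1, 4).sum(axis=2)
            reported = inputs.reported.get(t, np.zeros(annual.shape[1]))
            if np.any(annual < reported[None, :] - 1e-6):
                return False
            if t == "citn":
                # pass-through channel: distributions ARE the ledger
                continue
            deliv = _annual(inputs.deliveries.get(t, np.zeros(4 * annual.shape[1])))
            cum_d = np.cumsum(deliv)[None, :]
            if np.any(np.cumsum(annual, axis=1) > cum_d + 1e-6):
                return False
        return True


def _annual(quarterly: np.ndarray) -> np.ndarray:
    return np.asarray(quarterly, float).reshape(-1, 4).sum(axis=1)


def _sigmoid(x):
    from scipy.special import expit
    return expit(np.asarray(x, dtype=float))


def survey_crop_estimate(survey: pd.DataFrame,
                         national_household_count: float) -> tuple[float, float]:
    """National crop estimate from survey microdata, with cluster-robust SE.

    estimate = mean nets per household x national household count; the SE
    scales the standard error of the per-household mean computed from the
    variance of cluster means (clusters as primary sampling units). With a
    single cluster the plain household-level SE is used.
    """
    if len(survey) == 0:
        raise ValueError("empty survey")
    nets = (survey["n_citn"] + survey["n_llin"]).astype(float)
    est = float(nets.mean()) * national_household_count
    cl_means = nets.groupby(survey["cluster_id"]).mean()
    if len(cl_means) > 1:
        se_mean = float(cl_means.std(ddof=1)) / np.sqrt(len(cl_means))
    elif len(nets) > 1:
        se_mean = float(nets.std(ddof=1)) / np.sqrt(len(nets))
    else:
        se_mean = 0.0
    return est, se_mean * national_household_count


class _Model:
    """Log-posterior for the ensemble sampler.

    Parameter vector: [tau-score per net type..., u-score_1..u-score_nyears,
    s_1..s_3 quarterly-allocation softmax scores]. Bounded quantities are
    parameterised unbounded through a sigmoid with a standard-logistic
    prior on the score, which makes the implied prior exactly uniform —
    tau ~ U[1, 6] years, distribution fraction u ~ U[0, 1] — while keeping
    the ensemble moves free of hard walls. Net types with
    delivery=distribution (cITN) contribute a tau but no u parameters.

    Within a year, the annual distributed total is allocated to quarters
    proportionally to the estimated seasonal profile times each quarter's
    stock inflow (carry-over entering the year plus that quarter's
    deliveries): nets are mostly handed out soon after they arrive, which is
    how mass campaigns operate, and the quarterly delivery series carries
    the campaign timing.
    """

    def __init__(self, inputs: CountryInputs, k_steepness: float):
        self.inputs = inputs
        self.k = k_steepness
        self.types = sorted(set(inputs.deliveries) | set(inputs.reported))
        # a type is 'free' if its distributions are latent (deliveries ledger
        # exists separately from reports); cITN is pass-through
        self.free_types = [t for t in self.types if t != "citn"]
        self.n_years = inputs.n_years
        self.ndim = len(self.types) + len(self.free_types) * self.n_years + 3
        self.surveys = list(inputs.surveys)

    # --- parameter unpacking -------------------------------------------------
    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        i = len(self.types)
        lo, hi = TAU_PRIOR
        taus = dict(zip(self.types, lo + (hi - lo) * _sigmoid(theta[:i])))
        us = {}
        for t in self.free_types:
            us[t] = _sigmoid(theta[i:i + self.n_years])
            i += self.n_years
        scores = np.concatenate([[0.0], theta[i:i + 3]])
        e = np.exp(scores - scores.max())
        return taus, us, e / e.sum()

    def quarterly_distributed(self, us, w) -> dict:
        """Latent quarterly distributions per type, satisfying the bounds.

        Within each year the distribution is ``reported + u * (ceiling -
        reported)``. The ceiling is available stock minus a backward-computed
        *reserve*: the stock that must be carried forward so that every
        future year's reported floor stays reachable. Given globally feasible
        inputs, floor <= ceiling in every year for any u path.
        """
        out = {}
        for t in self.types:
            ny = self.n_years
            deliv_q = self.inputs.deliveries.get(t, np.zeros(4 * ny))
            reported = self.inputs.reported.get(t, np.zeros(ny))
            deliv_a = _annual(deliv_q)
            if t == "citn":
                # delivery = distribution: annual reported counts
                annual = reported.copy()
            else:
                reserve = np.zeros(ny)
                for y in range(ny - 2, -1, -1):
                    reserve[y] = max(0.0,
                                     reported[y + 1] - deliv_a[y + 1] + reserve[y + 1])
                annual = np.empty(ny)
                carry = 0.0
                for y in range(ny):
                    avail = carry + deliv_a[y]
                    lo = reported[y]
                    hi = max(avail - reserve[y], lo)
                    annual[y] = lo + us[t][y] * (hi - lo)
                    carry = avail - annual[y]
            # within-year split: seasonal profile x quarterly stock inflow
            q_dist = np.empty(4 * ny)
            carry_in = 0.0
            for y in range(ny):
                inflow = deliv_q[4 * y: 4 * y + 4].copy()
                inflow[0] += carry_in
                wq = w * inflow
                tot = wq.sum()
                wq = wq / tot if tot > 0 else w
                q_dist[4 * y: 4 * y + 4] = annual[y] * wq
                carry_in = max(inflow.sum() - annual[y], 0.0)
            out[t] = q_dist
        return out

    def crop_total(self, taus, dist_q) -> np.ndarray:
        total = np.zeros(self.inputs.n_quarters)
        for t, d in dist_q.items():
            curve = curve_from_retention(taus[t], k=self.k)
            total += quarterly_crop(d, curve)
        return total

    # --- posterior -----------------------------------------------------------
    def log_prob(self, theta):
        theta = np.asarray(theta, dtype=float)
        taus, us, w = self.unpack(theta)
        # standard-logistic prior on sigmoid scores => uniform on (tau, u)
        scores = theta[:-3]
        lp = float(np.sum(scores - 2.0 * np.logaddexp(0.0, scores)))
        lp += -0.5 * np.sum(theta[-3:] ** 2)  # N(0,1) on allocation scores
        dist_q = self.quarterly_distributed(us, w)
        crop = self.crop_total(taus, dist_q)
        for q, est, se in self.surveys:
            se_eff = max(se, 0.01 * abs(est))
            if se_eff == 0:
                se_eff = 1.0
            lp += -0.5 * ((est - crop[q]) / se_eff) ** 2 - np.log(se_eff)
        return lp

    def initial_state(self, n_walkers: int, rng: np.random.Generator):
        p0 = np.empty((n_walkers, self.ndim))
        n_scores = self.ndim - 3
        p0[:, :n_scores] = rng.logistic(size=(n_walkers, n_scores))
        p0[:, n_scores:] = 0.1 * rng.standard_normal((n_walkers, 3))
        return p0


def _split_rhat(chain: np.ndarray) -> float:
    """Gelman-Rubin statistic over walkers (steps, walkers)."""
    n, m = chain.shape
    half = n // 2
    if half < 2:
        return np.nan
    segments = np.concatenate([chain[:half], chain[half:2 * half]], axis=1)
    means = segments.mean(axis=0)
    variances = segments.var(axis=0, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W)) if W > 0 else 1.0


def fit_stock_and_flow(inputs: CountryInputs,
                       k_steepness: float = 20.0,
                       settings: MCMCSettings | None = None) -> StockFlowPosterior:
    """Fit the stock-and-flow model for one country.

    Raises ``ValueError`` when reported distributions are infeasible (their
    cumulative total exceeds cumulative deliveries). A fit without any survey
    estimate runs on the priors alone and is flagged ``low_confidence``.
    Non-convergence (split R-hat > 1.05 on any retention parameter) sets
    ``converged=False`` and emits a warning.
    """
    settings = settings or MCMCSettings()
    model = _Model(inputs, k_steepness)

    for t in model.free_types:
        rep = inputs.reported.get(t)
        if rep is None:
            continue
        cum_rep = np.cumsum(rep)
        cum_del = np.cumsum(_annual(inputs.deliveries.get(t, np.zeros(4 * inputs.n_years))))
        if np.any(cum_rep > cum_del + 1e-6):
            y = int(np.nonzero(cum_rep > cum_del + 1e-6)[0][0])
            raise ValueError(
                f"infeasible inputs for '{t}': cumulative reported distributions "
                f"({cum_rep[y]:.0f}) exceed cumulative deliveries ({cum_del[y]:.0f}) "
                f"by year index {y}"
            )

    rng = np.random.default_rng(settings.seed)
    n_walkers = max(settings.n_walkers, 2 * model.ndim + 2)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, model.ndim, model.log_prob,
                                    moves=moves)
    sampler.random_state = np.random.RandomState(settings.seed).get_state()
    p0 = model.initial_state(n_walkers, rng)
    sampler.run_mcmc(p0, settings.n_steps, progress=False)

    chain = sampler.get_chain(discard=settings.n_burn, thin=settings.thin)
    flat = chain.reshape(-1, model.ndim)

    lo, hi = TAU_PRIOR
    rhat = {}
    for j, t in enumerate(model.types):
        rhat[f"tau_{t}"] = _split_rhat(lo + (hi - lo) * _sigmoid(chain[:, :, j]))
    converged = all(np.isnan(v) or v <= 1.05 for v in rhat.values())
    if not converged:
        import warnings
        warnings.warn(f"stock-and-flow sampler not converged: R-hat {rhat}")

    # evaluate latent series on each retained draw
    n_draws = flat.shape[0]
    nq = inputs.n_quarters
    crop = np.zeros((n_draws, nq))
    crop_by_type = {t: np.zeros((n_draws, nq)) for t in model.types}
    distributed = {t: np.zeros((n_draws, nq)) for t in model.types}
    tau = {t: lo + (hi - lo) * _sigmoid(flat[:, j])
           for j, t in enumerate(model.types)}
    for i in range(n_draws):
        taus, us, w = model.unpack(flat[i])
        dq = model.quarterly_distributed(us, w)
        for t in model.types:
            distributed[t][i] = dq[t]
            ct = quarterly_crop(dq[t], curve_from_retention(taus[t], k=k_steepness))
            crop_by_type[t][i] = ct
            crop[i] += ct
    pop_q = np.repeat(inputs.population, 4).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        npc = np.where(pop_q[None, :] > 0, crop / pop_q[None, :], 0.0)

    summary = pd.DataFrame({
        "quarter": np.arange(nq),
        "year_frac": np.arange(nq) * QUARTER_YEARS,
        "crop_mean": crop.mean(axis=0),
        "crop_lo": np.quantile(crop, 0.025, axis=0),
        "crop_hi": np.quantile(crop, 0.975, axis=0),
        "npc_mean": npc.mean(axis=0),
        "npc_lo": np.quantile(npc, 0.025, axis=0),
        "npc_hi": np.quantile(npc, 0.975, axis=0),
    })
    return StockFlowPosterior(
        tau=tau, distributed=distributed, crop=crop, crop_by_type=crop_by_type,
        npc=npc, summary=summary, rhat=rhat,
        low_confidence=len(inputs.surveys) == 0, converged=converged,
    )
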