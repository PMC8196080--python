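"""Synthetic-data generator: a known ground truth for the whole pipeline.

Real inputs to national net-coverage estimation are manufacturer delivery
ledgers, programme distribution reports, and nationally representative
household surveys — none of which ship with this package. This module builds
a complete synthetic world with the same structure and the same failure
modes, so every downstream stage can be tested against a known truth:

* triennial mass-campaign delivery spikes plus a continuous routine channel;
* true distributions bounded by available stock, with reports capturing only
  a fraction of them (under-reporting);
* net attrition along the compact-support loss curve, so the true national
  crop satisfies the distribution-convolution identity exactly;
* a saturating net-to-household allocation with a misallocation dial ``m``:
  at ``m = 0`` nets go to the households that need them most and population
  access equals ``min(1, 2 * NPC)`` exactly; at ``m > 0`` a share of nets is
  dropped on random households (capped at one net per person), reproducing
  the observed plateau of access against nets-per-capita;
* seasonal, spatially varying net use conditional on access, with occasional
  three-to-a-net sharing so use can locally exceed access;
* Matern-covariance deviation fields with an AR1 quarter-to-quarter
  evolution and a linear covariate effect — the same family the
  geostatistical stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .loss import LossCurve, curve_from_retention, quarterly_crop
from .gp import GPHyperparams, matern32
from .rasters import grid_coords

__all__ = [
    "SyntheticConfig", "SyntheticWorld", "CountryWorld",
    "allocate_nets_to_households", "allocation_curve",
    "generate_delivery_and_distribution", "generate_rasters",
    "generate_survey", "build_world", "default_household_size_pmf",
]


def default_household_size_pmf() -> np.ndarray:
    """Household-size distribution over 1..15 persons, mean ~4.8 — the shape
    typical of sub-Saharan African survey data (mode at 4, long right tail)."""
    w = np.array([4, 7, 11, 14, 13, 11, 9, 7, 6, 5, 4, 3, 2.5, 2, 1.5])
    return w / w.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world. Defaults follow the planning
    quantities of the domain: campaigns every 3 years procuring one net per
    1.8 people at risk (0.56 NPC), LLIN median retention 2 years."""

    country_ids: tuple = ("ALPHA", "BETA")
    year_start: int = 2000
    year_end: int = 2020                       # inclusive
    campaign_period_years: int = 3
    campaign_size_npc: float = 1.0 / 1.8       # WHO procurement: net per 1.8 people
    continuous_rate: float = 0.03              # nets per person-year, routine channels
    true_tau_llin: float = 2.0                 # years, median retention
    true_tau_citn: float = 1.5
    loss_k: float = 20.0
    citn_years: int = 6                        # cITN channel active in early years only
    citn_rate: float = 0.01                    # nets per person-year
    reporting_fraction: float = 0.9
    misallocation: float = 0.5
    household_size_pmf: np.ndarray = field(default_factory=default_household_size_pmf)
    use_propensity_base: float = 1.6           # logit scale
    use_seasonal_amplitude: float = 0.6
    net_sharing_excess: float = 0.05
    grid_shape: tuple = (30, 30)
    cluster_count: int = 50
    households_per_cluster: int = 20
    spatial_range: float = 8.0                 # grid units, Matern range of truth fields
    access_dev_sd: float = 0.08                # marginal sd of NPC-deviation truth
    use_dev_sd: float = 0.5                    # logit-scale sd of use-propensity field
    phi_time: float = 0.85                     # AR1 quarter-to-quarter coefficient
    covariate_effect: float = 0.5              # linear loading of the covariate raster
    population_mean: float = 500.0             # persons per populated pixel
    seed: int = 0

    def __post_init__(self) -> None:
        pmf = np.asarray(self.household_size_pmf, dtype=float)
        if pmf.size != 15 or np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("household_size_pmf must be a 15-vector summing to 1")
        self.household_size_pmf = pmf
        for name in ("reporting_fraction", "misallocation", "net_sharing_excess"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reporting_fraction <= 0:
            raise ValueError("reporting_fraction must be in (0, 1]")
        if self.campaign_period_years < 1:
            raise ValueError("campaign_period_years must be >= 1")
        if self.grid_shape[0] * self.grid_shape[1] < self.cluster_count:
            raise ValueError("grid must have at least cluster_count cells")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def n_quarters(self) -> int:
        return 4 * self.n_years

    @property
    def llin_curve(self) -> LossCurve:
        return curve_from_retention(self.true_tau_llin, k=self.loss_k)

    @property
    def citn_curve(self) -> LossCurve:
        return curve_from_retention(self.true_tau_citn, k=self.loss_k)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["household_size_pmf"] = [float(x) for x in self.household_size_pmf]
        d["country_ids"] = list(self.country_ids)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["country_ids"] = tuple(d["country_ids"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["household_size_pmf"] = np.asarray(d["household_size_pmf"], float)
        return cls(**d)


# --------------------------------------------------------------------------
# net allocation
# --------------------------------------------------------------------------

def allocate_nets_to_households(total_nets: int, sizes, m: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Assign ``total_nets`` to households, one net at a time.

    With probability ``1 - m`` a net goes to the household with the greatest
    unmet need (``ceil(size / 2) - nets``, ties broken by lowest index);
    otherwise it lands on a uniformly random household, capped at ``size``
    nets. ``m`` is the misallocation dial: 0 is perfectly targeted, 1 fully
    random.
    """
    sizes = np.asarray(sizes, dtype=int)
    if total_nets < 0 or not (0.0 <= m <= 1.0):
        raise ValueError("total_nets >= 0 and m in [0, 1] required")
    capacity = int(sizes.sum())
    if total_nets > capacity:
        raise ValueError(f"cannot place {total_nets} nets in capacity {capacity}")
    nets = np.zeros(sizes.size, dtype=int)
    need = np.ceil(sizes / 2).astype(int)
    misdirected = rng.random(total_nets) < m
    for i in range(total_nets):
        if misdirected[i]:
            open_hh = np.nonzero(nets < sizes)[0]
            j = open_hh[rng.integers(open_hh.size)]
        else:
            unmet = need - nets
            j = int(np.argmax(unmet))
            if unmet[j] <= 0:  # all needs met: fall back to any household with room
                open_hh = np.nonzero(nets < sizes)[0]
                j = open_hh[rng.integers(open_hh.size)]
        nets[j] += 1
    return nets


def allocation_curve(m: float, size_pmf: np.ndarray, seed: int,
                     n_households: int = 600,
                     npc_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Monte-Carlo map from NPC to expected population access (and sharing
    slack) under the allocation mechanism at misallocation ``m``.

    Returns a DataFrame with columns npc, access, extras (expected spare
    third-sleeper slots per person). Used both as the ground-truth
    access surface and as calibration pairs for crop-to-access conversion.
    """
    rng = np.random.default_rng(seed)
    if npc_grid is None:
        npc_grid = np.arange(0.0, 0.921, 0.04)
    sizes = rng.choice(np.arange(1, 16), size=n_households, p=size_pmf)
    pop = int(sizes.sum())
    rows = []
    for npc in npc_grid:
        total = min(int(round(npc * pop)), pop)
        nets = allocate_nets_to_households(total, sizes, m, rng)
        covered = np.minimum(2 * nets, sizes)
        extras = np.minimum(nets, sizes - covered)
        rows.append({"npc": npc, "access": covered.sum() / pop,
                     "extras": extras.sum() / pop})
    return pd.DataFrame(rows)


def _interp_curve(curve: pd.DataFrame, col: str, npc_values: np.ndarray) -> np.ndarray:
    return np.interp(npc_values, curve["npc"].to_numpy(), curve[col].to_numpy())


# --------------------------------------------------------------------------
# national delivery / distribution series
# --------------------------------------------------------------------------

def generate_delivery_and_distribution(config: SyntheticConfig,
                                       population: float, rng: np.random.Generator):
    """National annual delivery and (under-)reported distribution tables for
    one country, plus the true quarterly distribution and delivery series per
    net type. Returns ``(deliveries, distributions, true_dist, deliv_q)``.

    Mass campaigns arrive every ``campaign_period_years``; routine deliveries
    are continuous. True distributions empty a fixed fraction of available
    stock per quarter (high in campaign quarters), so cumulative true
    distributions never exceed cumulative deliveries by construction.
    Reported distributions are ``reporting_fraction`` of the truth, rounded.
    """
    ny, nq = config.n_years, config.n_quarters
    deliv_q = {"llin": np.zeros(nq), "citn": np.zeros(nq)}
    for y in range(ny):
        base = config.continuous_rate * population / 4.0
        deliv_q["llin"][4 * y: 4 * y + 4] += base
        if y % config.campaign_period_years == 0:
            # campaign procurement lands in the first half of the year
            total = config.campaign_size_npc * population
            deliv_q["llin"][4 * y] += 0.6 * total
            deliv_q["llin"][4 * y + 1] += 0.4 * total
        if y < config.citn_years:
            deliv_q["citn"][4 * y: 4 * y + 4] += config.citn_rate * population / 4.0

    true_dist = {}
    for t, dq in deliv_q.items():
        dist = np.zeros(nq)
        stock = 0.0
        for q in range(nq):
            stock += dq[q]
            campaign_q = (q // 4) % config.campaign_period_years == 0 and q % 4 in (0, 1)
            frac = 0.85 if (t == "llin" and campaign_q) else 0.35
            dist[q] = frac * stock
            stock -= dist[q]
        true_dist[t] = dist

    deliveries = []
    distributions = []
    for t in ("llin", "citn"):
        annual_deliv = deliv_q[t].reshape(ny, 4).sum(axis=1)
        annual_true = true_dist[t].reshape(ny, 4).sum(axis=1)
        for y in range(ny):
            year = config.year_start + y
            deliveries.append({"year": year, "net_type": t,
                               "count": round(annual_deliv[y])})
            # cITN reports are complete (delivery = distribution); LLIN
            # reports capture only reporting_fraction of the truth
            f = 1.0 if t == "citn" else config.reporting_fraction
            distributions.append({"year": year, "net_type": t,
                                  "count": round(f * annual_true[y])})
    return pd.DataFrame(deliveries), pd.DataFrame(distributions), true_dist, deliv_q


# --------------------------------------------------------------------------
# rasters and truth fields
# --------------------------------------------------------------------------

class _FieldSampler:
    """Draws zero-mean unit-variance Matern-3/2 fields on the grid."""

    def __init__(self, shape, spatial_range, rng: np.random.Generator):
        coords = grid_coords(shape)
        from scipy.spatial.distance import cdist
        hyper = GPHyperparams(sigma2=1.0, rho=spatial_range, phi=0.0, nugget=0.0)
        K = matern32(cdist(coords, coords), hyper) + 1e-8 * np.eye(coords.shape[0])
        self._L = np.linalg.cholesky(K)
        self._shape = shape
        self._rng = rng

    def draw(self) -> np.ndarray:
        z = self._rng.standard_normal(self._L.shape[0])
        return (self._L @ z).reshape(self._shape)

    def ar1_series(self, n: int, phi: float) -> np.ndarray:
        """Stationary AR1 sequence of fields, unit marginal variance."""
        out = np.empty((n, *self._shape))
        out[0] = self.draw()
        for i in range(1, n):
            out[i] = phi * out[i - 1] + np.sqrt(1 - phi ** 2) * self.draw()
        return out


def generate_rasters(config: SyntheticConfig, rng: np.random.Generator):
    """Population raster, covariate raster, and quarterly deviation truth.

    Returns dict with population, mask, covariate, and the AR1-evolving
    standardised fields ``npc_field`` and ``use_field`` of shape
    (n_quarters, rows, cols), each including the linear covariate effect.
    """
    sampler = _FieldSampler(config.grid_shape, config.spatial_range, rng)
    pop_field = sampler.draw()
    population = config.population_mean * np.exp(0.5 * pop_field - 0.125)
    mask = population > np.quantile(population, 0.05)
    covariate = sampler.draw()

    def dressed(raw):  # covariate effect + GP, restandardised to unit variance
        s = np.sqrt(1.0 + config.covariate_effect ** 2)
        return (raw + config.covariate_effect * covariate[None, :, :]) / s

    npc_field = dressed(sampler.ar1_series(config.n_quarters, config.phi_time))
    use_field = dressed(sampler.ar1_series(config.n_quarters, config.phi_time))
    return {"population": population, "mask": mask, "covariate": covariate,
            "npc_field": npc_field, "use_field": use_field}


# --------------------------------------------------------------------------
# the world
# --------------------------------------------------------------------------

@dataclass
class CountryWorld:
    """Everything true and observable for one synthetic country."""

    country: str
    population_raster: np.ndarray
    mask: np.ndarray
    covariate: np.ndarray
    deliveries: pd.DataFrame        # annual, by net type
    distributions: pd.DataFrame     # annual reported, by net type
    true_deliveries_q: dict         # net type -> quarterly delivery counts
    true_distributed: dict          # net type -> quarterly counts
    true_crop: dict                 # net type -> quarterly counts
    true_npc: np.ndarray            # national, quarterly
    true_access: np.ndarray         # national, quarterly
    npc_surface: np.ndarray         # (nq, rows, cols)
    access_surface: np.ndarray
    use_surface: np.ndarray         # evaluated at mid-quarter month
    use_field: np.ndarray           # logit-scale pixel use-propensity offsets

    @property
    def population(self) -> float:
        return float(self.population_raster[self.mask].sum())


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    countries: dict
    alloc_curve: pd.DataFrame       # npc -> expected access/extras at config.m

    def quarter_of(self, year: int, month: int) -> int:
        q = (year - self.config.year_start) * 4 + (month - 1) // 3
        if not (0 <= q < self.config.n_quarters):
            raise ValueError(f"{year}-{month:02d} outside the simulated horizon")
        return q


def _seasonal_logit(config: SyntheticConfig, month: int) -> float:
    return config.use_propensity_base + config.use_seasonal_amplitude * np.sin(
        2.0 * np.pi * month / 12.0)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def build_world(config: SyntheticConfig) -> SyntheticWorld:
    """Assemble the full synthetic world from the configuration.

    Identical config + seed gives byte-identical tables: all randomness flows
    from one seeded generator per country plus one for the allocation curve.
    """
    alloc = allocation_curve(config.misallocation, config.household_size_pmf,
                             seed=config.seed + 90001)
    countries = {}
    for ci, cid in enumerate(config.country_ids):
        rng = np.random.default_rng([config.seed, 1000 + ci])
        rasters = generate_rasters(config, rng)
        population = float(rasters["population"][rasters["mask"]].sum())
        deliv, dist, true_dist, deliv_q = generate_delivery_and_distribution(
            config, population, rng)
        deliv.insert(0, "country", cid)
        dist.insert(0, "country", cid)
        true_crop = {
            "llin": quarterly_crop(true_dist["llin"], config.llin_curve),
            "citn": quarterly_crop(true_dist["citn"], config.citn_curve),
        }
        crop_total = true_crop["llin"] + true_crop["citn"]
        nat_npc = crop_total / population
        nat_access = _interp_curve(alloc, "access", nat_npc)

        npc_surface = np.maximum(
            nat_npc[:, None, None]
            + config.access_dev_sd * rasters["npc_field"], 0.0)
        access_surface = _interp_curve(
            alloc, "access", npc_surface.ravel()).reshape(npc_surface.shape)
        extras_surface = _interp_curve(
            alloc, "extras", npc_surface.ravel()).reshape(npc_surface.shape)
        nq = config.n_quarters
        mid_months = np.array([(q % 4) * 3 + 2 for q in range(nq)])
        season = np.array([_seasonal_logit(config, m) for m in mid_months])
        p_use = _logistic(season[:, None, None]
                          + config.use_dev_sd * rasters["use_field"])
        use_surface = np.minimum(
            p_use * (access_surface
                     + config.net_sharing_excess * extras_surface), 1.0)

        countries[cid] = CountryWorld(
            country=cid,
            population_raster=rasters["population"],
            mask=rasters["mask"],
            covariate=rasters["covariate"],
            deliveries=deliv, distributions=dist,
            true_deliveries_q=deliv_q,
            true_distributed=true_dist, true_crop=true_crop,
            true_npc=nat_npc, true_access=nat_access,
            npc_surface=npc_surface, access_surface=access_surface,
            use_surface=use_surface, use_field=rasters["use_field"],
        )
    return SyntheticWorld(config=config, countries=countries, alloc_curve=alloc)


# --------------------------------------------------------------------------
# survey generation
# --------------------------------------------------------------------------

def generate_survey(world: SyntheticWorld, country: str, year: int, month: int,
                    survey_id: str | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one cluster household survey from the synthetic world.

    Clusters are pixels sampled with probability proportional to population;
    household sizes follow the configured PMF; nets are placed by the
    allocation mechanism at the pixel's true NPC; each person with access
    sleeps under a net with the month's logistic use probability (plus the
    pixel's propensity offset), and each net hosts a third sleeper with
    probability ``net_sharing_excess``.
    """
    config = world.config
    if country not in world.countries:
        raise KeyError(f"unknown country {country!r}")
    cw = world.countries[country]
    q = world.quarter_of(year, month)
    country_key = sum(country.encode()) % 2 ** 16  # stable across interpreter runs
    rng = rng if rng is not None else np.random.default_rng(
        [config.seed, country_key, year, month])
    survey_id = survey_id or f"{country}-{year}-{month:02d}"

    rows_idx, cols_idx = np.nonzero(cw.mask)
    weights = cw.population_raster[cw.mask]
    chosen = rng.choice(rows_idx.size, size=config.cluster_count, replace=False,
                        p=weights / weights.sum())
    citn_share = (cw.true_crop["citn"][q]
                  / max(cw.true_crop["citn"][q] + cw.true_crop["llin"][q], 1e-12))

    records = []
    for c_i, cell in enumerate(chosen):
        r, c = int(rows_idx[cell]), int(cols_idx[cell])
        sizes = rng.choice(np.arange(1, 16), size=config.households_per_cluster,
                           p=config.household_size_pmf)
        pop = int(sizes.sum())
        local_npc = cw.npc_surface[q, r, c]
        total_nets = min(rng.poisson(local_npc * pop), pop)
        nets = allocate_nets_to_households(total_nets, sizes, config.misallocation, rng)
        p_use = _logistic(_seasonal_logit(config, month)
                          + config.use_dev_sd * cw.use_field[q, r, c])
        for h in range(config.households_per_cluster):
            covered = min(2 * nets[h], sizes[h])
            sleepers = rng.binomial(covered, p_use)
            spare = min(nets[h], sizes[h] - covered)
            if spare > 0 and config.net_sharing_excess > 0:
                sleepers += rng.binomial(spare, config.net_sharing_excess * p_use)
            n_citn = rng.binomial(nets[h], citn_share)
            records.append({
                "survey_id": survey_id, "cluster_id": c_i,
                "lon": float(c), "lat": float(r),
                "year": year, "month": month, "hh_id": h,
                "defacto_size": int(sizes[h]),
                "n_citn": int(n_citn), "n_llin": int(nets[h] - n_citn),
                "sleepers_under_nets": int(sleepers),
            })
    return pd.DataFrame(records)
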