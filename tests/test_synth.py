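"""Synthetic-world contracts: allocation mechanism, conservation, stock rule,
reporting, field structure, survey realism, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import itncover as ic
from itncover.loss import quarterly_crop
from itncover.synth import (SyntheticConfig, _FieldSampler, allocation_curve,
                            generate_delivery_and_distribution)


class TestAllocation:
    def test_perfect_pairing(self, rng):
        sizes = np.full(50, 2)
        nets = ic.allocate_nets_to_households(50, sizes, 0.0, rng)
        assert np.all(nets == 1)

    def test_sums_to_total(self, rng):
        sizes = rng.integers(1, 10, 100)
        nets = ic.allocate_nets_to_households(150, sizes, 0.4, rng)
        assert nets.sum() == 150
        assert np.all(nets <= sizes)

    def test_m0_access_is_linear_in_npc_for_even_sizes(self, rng):
        sizes = np.concatenate([np.full(100, 2), np.full(50, 4), np.full(25, 6)])
        pop = int(sizes.sum())
        for total in (55, 137, 220, 275, 330):
            nets = ic.allocate_nets_to_households(total, sizes, 0.0, rng)
            access = np.minimum(2 * nets, sizes).sum() / pop
            assert access == pytest.approx(min(1.0, 2 * total / pop), abs=1e-12)

    def test_misallocation_saturates_access(self):
        rng = np.random.default_rng(7)
        sizes = np.full(500, 2)
        nets = ic.allocate_nets_to_households(500, sizes, 1.0, rng)
        access = np.minimum(2 * nets, sizes).sum() / sizes.sum()
        assert access < 1.0  # NPC = 0.5, linear prediction would be 1.0

    def test_overflow_rejected(self, rng):
        with pytest.raises(ValueError, match="cannot place"):
            ic.allocate_nets_to_households(11, np.full(5, 2), 0.0, rng)

    def test_allocation_curve_monotone_in_npc(self):
        curve = allocation_curve(0.5, ic.synth.default_household_size_pmf(), seed=1)
        assert np.all(np.diff(curve["access"]) >= -0.02)  # MC noise tolerance


class TestDeliveryDistribution:
    def test_full_reporting_is_identity(self):
        cfg = SyntheticConfig(reporting_fraction=1.0)
        rng = np.random.default_rng(0)
        _, dist, true_dist, _ = generate_delivery_and_distribution(cfg, 1e5, rng)
        annual_true = true_dist["llin"].reshape(-1, 4).sum(axis=1)
        reported = dist.query("net_type == 'llin'")["count"].to_numpy(float)
        assert reported == pytest.approx(annual_true, abs=0.5)  # rounding only

    def test_conservation_single_campaign(self):
        cfg = SyntheticConfig(continuous_rate=0.0, citn_rate=0.0,
                              campaign_period_years=50, campaign_size_npc=0.5)
        rng = np.random.default_rng(0)
        _, _, true_dist, deliv_q = generate_delivery_and_distribution(cfg, 2e6, rng)
        # one campaign of 1e6 nets: distributions approach deliveries over the horizon
        assert deliv_q["llin"].sum() == pytest.approx(1e6)
        assert true_dist["llin"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_stock_rule_every_quarter(self, world):
        for cw in world.countries.values():
            for t in ("llin", "citn"):
                cum_dist = np.cumsum(cw.true_distributed[t])
                cum_deliv = np.cumsum(cw.true_deliveries_q[t])
                assert np.all(cum_dist <= cum_deliv + 1e-6)

    def test_campaign_spikes(self, world):
        cw = world.countries["ALPHA"]
        annual = cw.deliveries.query("net_type == 'llin'")["count"].to_numpy(float)
        camp = annual[::world.config.campaign_period_years]
        routine = np.delete(annual, slice(None, None, world.config.campaign_period_years))
        assert camp.min() > 5 * routine.max()


class TestWorldTruth:
    def test_crop_conservation_identity(self, world):
        cfg = world.config
        for cw in world.countries.values():
            assert cw.true_crop["llin"] == pytest.approx(
                quarterly_crop(cw.true_distributed["llin"], cfg.llin_curve))

    def test_truth_surfaces_in_domain(self, world):
        for cw in world.countries.values():
            assert np.all((cw.access_surface >= 0) & (cw.access_surface <= 1))
            assert np.all((cw.use_surface >= 0) & (cw.use_surface <= 1))
            assert np.all(cw.npc_surface >= 0)
            assert np.all(cw.population_raster >= 0)

    def test_empirical_variogram_increases_with_distance(self):
        rng = np.random.default_rng(11)
        sampler = _FieldSampler((25, 25), spatial_range=8.0, rng=rng)
        f = sampler.draw()
        # semivariance at lag h along rows, averaged over several draws
        gammas = []
        for h in (1, 4, 8):
            g = np.mean([(np.mean((s[h:, :] - s[:-h, :]) ** 2) / 2)
                         for s in (sampler.draw() for _ in range(8))])
            gammas.append(g)
        assert gammas[0] < gammas[1] < gammas[2]

    def test_reproducibility_byte_identical(self):
        cfg = SyntheticConfig(country_ids=("ALPHA",), seed=12)
        w1 = ic.build_world(cfg)
        w2 = ic.build_world(SyntheticConfig(country_ids=("ALPHA",), seed=12))
        s1 = ic.generate_survey(w1, "ALPHA", 2010, 6)
        s2 = ic.generate_survey(w2, "ALPHA", 2010, 6)
        assert s1.to_csv() == s2.to_csv()
        pd.testing.assert_frame_equal(w1.countries["ALPHA"].deliveries,
                                      w2.countries["ALPHA"].deliveries)


class TestSurvey:
    def test_saturated_use_equals_access(self, world):
        cfg = SyntheticConfig(country_ids=("ALPHA",), seed=3,
                              use_propensity_base=50.0, use_seasonal_amplitude=0.0,
                              net_sharing_excess=0.0)
        w = ic.build_world(cfg)
        s = ic.generate_survey(w, "ALPHA", 2012, 6)
        agg = ic.cluster_aggregates(s)
        assert agg["use"].to_numpy() == pytest.approx(agg["access"].to_numpy())

    def test_zero_propensity_means_zero_use(self):
        cfg = SyntheticConfig(country_ids=("ALPHA",), seed=3,
                              use_propensity_base=-50.0, net_sharing_excess=0.0)
        w = ic.build_world(cfg)
        s = ic.generate_survey(w, "ALPHA", 2012, 6)
        assert s["sleepers_under_nets"].sum() == 0

    def test_unknown_country_and_bad_month(self, world):
        with pytest.raises(KeyError):
            ic.generate_survey(world, "NOWHERE", 2010, 6)
        with pytest.raises(ValueError):
            ic.generate_survey(world, "ALPHA", 2030, 6)

    def test_survey_crop_near_truth(self, world):
        """Survey-estimated national crop within 3 SE of truth in most of
        20 seeded replicate months."""
        cfg = world.config
        cw = world.countries["ALPHA"]
        mean_hh = float(np.arange(1, 16) @ cfg.household_size_pmf)
        n_hh = cw.population / mean_hh
        hits = 0
        cases = [(2004 + i % 15, m) for i, m in enumerate([3, 6, 9] * 7)][:20]
        for year, month in cases:
            s = ic.generate_survey(world, "ALPHA", year, month)
            est, se = ic.survey_crop_estimate(s, n_hh)
            q = world.quarter_of(year, month)
            truth = cw.true_crop["llin"][q] + cw.true_crop["citn"][q]
            if abs(est - truth) <= 3 * se:
                hits += 1
        assert hits >= 18


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"reporting_fraction": 1.5},
        {"misallocation": -0.1},
        {"campaign_period_years": 0},
        {"grid_shape": (3, 3), "cluster_count": 50},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_pmf_must_sum_to_one(self):
        pmf = np.ones(15)
        with pytest.raises(ValueError):
            SyntheticConfig(household_size_pmf=pmf)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back.seed == 9
        assert back.household_size_pmf == pytest.approx(cfg.household_size_pmf)
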