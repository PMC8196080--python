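"""Map composition, relative-gain counterfactuals, uncertainty displays."""

import numpy as np
import pytest

from itncover.surfaces import (compose_maps, exceedance, relative_gain,
                               uncertainty_classify)


def _draw_stack(n_draws, shape, value):
    return np.full((n_draws, *shape), value, dtype=float)


class TestComposeMaps:
    def _compose(self, nat_access, dA, gap, nat_npc=0.4, dN=0.0):
        shape = (4, 4)
        mask = np.ones(shape, bool)
        dev = {"access_deviation": _draw_stack(3, shape, dA),
               "use_gap_signed": _draw_stack(3, shape, gap),
               "npc_deviation": _draw_stack(3, shape, dN)}
        nat = {"access": np.full(3, nat_access), "npc": np.full(3, nat_npc)}
        return compose_maps(nat, dev, mask)

    def test_additive_composition(self):
        out = self._compose(0.5, -0.1, -0.05)
        assert out["access"].mean == pytest.approx(0.4)
        assert out["use"].mean == pytest.approx(0.35)

    def test_clamping_at_domain_edges(self):
        out = self._compose(0.95, 0.10, 0.0)
        assert out["access"].mean == pytest.approx(1.0)
        out = self._compose(0.05, -0.10, 0.0)
        assert out["access"].mean == pytest.approx(0.0)

    def test_preclamp_identity_every_draw_and_cell(self):
        rng = np.random.default_rng(0)
        shape = (6, 6)
        mask = np.ones(shape, bool)
        dev = {"access_deviation": rng.normal(0, 0.2, (20, *shape)),
               "use_gap_signed": rng.normal(0, 0.2, (20, *shape)),
               "npc_deviation": rng.normal(0, 0.1, (20, *shape))}
        nat = {"access": rng.uniform(0.3, 0.9, 20), "npc": rng.uniform(0.2, 0.5, 20)}
        out = compose_maps(nat, dev, mask)
        access = np.clip(out["access_preclamp_draws"], 0, 1)
        assert out["use_preclamp_draws"] - access == pytest.approx(dev["use_gap_signed"])

    def test_use_rate_flagged_on_zero_access(self):
        out = self._compose(0.0, 0.0, 0.0)
        assert np.all(np.isnan(out["use_rate"].mean))

    def test_masked_cells_are_missing(self):
        shape = (4, 4)
        mask = np.zeros(shape, bool)
        mask[0, 0] = True
        dev = {k: _draw_stack(3, shape, 0.0)
               for k in ("access_deviation", "use_gap_signed", "npc_deviation")}
        nat = {"access": np.full(3, 0.5), "npc": np.full(3, 0.4)}
        out = compose_maps(nat, dev, mask)
        assert np.isnan(out["access"].mean[1, 1])
        assert out["access"].mean[0, 0] == pytest.approx(0.5)


class TestRelativeGain:
    def test_worked_arithmetic(self):
        # access 0.6, use 0.48: rate 0.8 -> gains (0.12, 0.32)
        g_rate, g_access = relative_gain(np.array([0.6]), np.array([0.48]))
        assert g_rate[0] == pytest.approx(0.12)
        assert g_access[0] == pytest.approx(0.32)

    def test_no_gain_when_rate_is_one(self):
        g_rate, _ = relative_gain(np.array([0.7]), np.array([0.7]))
        assert g_rate[0] == pytest.approx(0.0)

    def test_no_gain_from_access_when_universal(self):
        _, g_access = relative_gain(np.array([1.0]), np.array([0.8]))
        assert g_access[0] == pytest.approx(0.0)

    def test_rate_capped_at_one_in_counterfactual(self):
        # sharing can push use above access; the access counterfactual
        # must not extrapolate a rate above 1
        _, g_access = relative_gain(np.array([0.5]), np.array([0.6]))
        assert g_access[0] == pytest.approx(1.0 - 0.6)

    def test_zero_access_flagged(self):
        g_rate, g_access = relative_gain(np.array([0.0]), np.array([0.0]))
        assert np.isnan(g_rate[0]) and np.isnan(g_access[0])

    def test_access_gain_dominates_when_rate_exceeds_access(self, rng):
        """Algebraic dominance: wherever use_rate > access, raising access
        to 1 yields more use than raising the rate to 1."""
        access = rng.uniform(0.05, 1.0, 2000)
        rate = rng.uniform(0.0, 1.0, 2000)
        use = access * rate
        g_rate, g_access = relative_gain(access, use)
        sel = (rate > access) & (rate < 1.0)
        assert sel.sum() > 100
        assert np.all(g_access[sel] > g_rate[sel])


class TestUncertaintyDisplays:
    def test_exceedance_trivial_bounds(self):
        draws = _draw_stack(50, (3, 3), 0.7)
        mask = np.ones((3, 3), bool)
        assert exceedance(draws, 0.1, mask) == pytest.approx(np.ones((3, 3)))
        assert exceedance(draws, 0.9, mask) == pytest.approx(np.zeros((3, 3)))

    def test_constant_mean_single_bin_warns(self):
        shape = (5, 5)
        mean = np.full(shape, 0.5)
        width = np.linspace(0, 1, 25).reshape(shape)
        pop = np.ones(shape)
        with pytest.warns(UserWarning, match="constant raster"):
            classes = uncertainty_classify(mean, width, pop, np.ones(shape, bool))
        assert set(classes.ravel() // 4) == {0}

    def test_uniform_population_bins_equally(self, rng):
        shape = (20, 20)
        mean = rng.uniform(0, 1, shape)
        width = rng.uniform(0, 1, shape)
        pop = np.ones(shape)
        classes = uncertainty_classify(mean, width, pop, np.ones(shape, bool), n_bins=4)
        mean_bins = classes.ravel() // 4
        counts = np.bincount(mean_bins, minlength=4)
        assert counts == pytest.approx(np.full(4, 100), abs=2)

    def test_n_bins_validated(self):
        a = np.ones((2, 2))
        with pytest.raises(ValueError):
            uncertainty_classify(a, a, a, np.ones((2, 2), bool), n_bins=1)
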