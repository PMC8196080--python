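"""Shared fixtures: one small synthetic world, one stock-and-flow fit and one
full pipeline run are built once per session and reused across test modules
to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import itncover as ic


SURVEY_YEARS = (2006, 2010, 2014, 2018)


@pytest.fixture(scope="session")
def world():
    cfg = ic.SyntheticConfig(country_ids=("ALPHA",), seed=3)
    return ic.build_world(cfg)


@pytest.fixture(scope="session")
def country_inputs(world):
    """CountryInputs for the single synthetic country, with 4 surveys."""
    cfg = world.config
    cw = world.countries["ALPHA"]
    mean_hh = float(np.arange(1, 16) @ cfg.household_size_pmf)
    surveys = []
    for year in SURVEY_YEARS:
        s = ic.generate_survey(world, "ALPHA", year, 6)
        est, se = ic.survey_crop_estimate(s, cw.population / mean_hh)
        surveys.append((world.quarter_of(year, 6), est, se))
    deliveries = {t: cw.true_deliveries_q[t].copy() for t in ("llin", "citn")}
    reported = {
        t: cw.distributions.query("net_type == @t")["count"].to_numpy(float)
        for t in ("llin", "citn")
    }
    return ic.CountryInputs(
        deliveries=deliveries, reported=reported,
        population=np.full(cfg.n_years, cw.population), surveys=surveys)


@pytest.fixture(scope="session")
def stockflow_fit(country_inputs):
    return ic.fit_stock_and_flow(
        country_inputs, settings=ic.MCMCSettings(seed=1))


@pytest.fixture(scope="session")
def single_survey_fit(country_inputs):
    inputs = ic.CountryInputs(
        deliveries=country_inputs.deliveries,
        reported=country_inputs.reported,
        population=country_inputs.population,
        surveys=country_inputs.surveys[2:3])
    return ic.fit_stock_and_flow(
        inputs, settings=ic.MCMCSettings(n_steps=2000, n_burn=1000, thin=20, seed=2))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = ic.RunConfig(out_dir=str(out), master_seed=7,
                       mcmc=ic.MCMCSettings(n_steps=2500, n_burn=1250, thin=25))
    manifest, state = ic.run_pipeline(cfg, return_state=True)
    return cfg, manifest, out, state


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_households(sizes, nets, sleepers=None):
    """Build a minimal household table for indicator tests."""
    sizes = np.asarray(sizes)
    nets = np.asarray(nets)
    sleepers = np.zeros_like(sizes) if sleepers is None else np.asarray(sleepers)
    n = sizes.size
    return pd.DataFrame({
        "survey_id": "s", "cluster_id": np.zeros(n, int),
        "lon": 0.0, "lat": 0.0, "year": 2010, "month": 6,
        "hh_id": np.arange(n), "defacto_size": sizes,
        "n_citn": np.zeros(n, int), "n_llin": nets,
        "sleepers_under_nets": sleepers,
    })
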