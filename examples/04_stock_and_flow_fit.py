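"""Fitting the stock-and-flow model to a synthetic country.

Simulates one country (true median retention 2.0 years), draws four
household surveys, and runs the Bayesian fit at reduced sampler settings.
Prints the recovered retention time with its credible interval and audits
the stock/report constraints on every posterior draw.
"""

import numpy as np

import itncover as ic

cfg = ic.SyntheticConfig(country_ids=("ALPHA",), seed=3)
world = ic.build_world(cfg)
cw = world.countries["ALPHA"]
mean_hh = float(np.arange(1, 16) @ cfg.household_size_pmf)

surveys = []
for year in (2006, 2010, 2014, 2018):
    s = ic.generate_survey(world, "ALPHA", year, 6)
    est, se = ic.survey_crop_estimate(s, cw.population / mean_hh)
    q = world.quarter_of(year, 6)
    print(f"survey {year}: crop estimate {est/1e3:.0f}k (SE {se/1e3:.0f}k), "
          f"true {(cw.true_crop['llin'][q] + cw.true_crop['citn'][q])/1e3:.0f}k")
    surveys.append((q, est, se))

inputs = ic.CountryInputs(
    deliveries={t: cw.true_deliveries_q[t].copy() for t in ("llin", "citn")},
    reported={t: cw.distributions.query("net_type == @t")["count"].to_numpy(float)
              for t in ("llin", "citn")},
    population=np.full(cfg.n_years, cw.population),
    surveys=surveys)

fit = ic.fit_stock_and_flow(
    inputs, settings=ic.MCMCSettings(n_steps=2000, n_burn=1000, thin=20, seed=1))
tau = fit.tau["llin"]
print(f"\nLLIN median retention: {np.median(tau):.2f} years "
      f"(95% CI {np.quantile(tau, 0.025):.2f}-{np.quantile(tau, 0.975):.2f}); "
      f"simulated truth {cfg.true_tau_llin}")
print("every draw respects the stock/report bounds:",
      fit.constraint_audit(inputs))
print("-> the sampler recovers how long households keep nets purely from "
      "delivery ledgers, reports and a handful of surveys.")
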