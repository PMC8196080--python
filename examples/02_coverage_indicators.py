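"""Survey coverage indicators: access, household-level access, use, use rate.

Builds a six-household micro-survey and prints each indicator with the
arithmetic behind it, including the canonical household of ten people with
three nets (six people have access, two per net).
"""

import pandas as pd

from itncover import (household_level_access, individual_access_count,
                      population_access, use_and_rate)

survey = pd.DataFrame({
    "survey_id": "demo", "cluster_id": 0, "lon": 0.0, "lat": 0.0,
    "year": 2019, "month": 6, "hh_id": range(6),
    "defacto_size": [10, 2, 5, 4, 3, 6],
    "n_citn": 0, "n_llin": [3, 1, 1, 2, 1, 0],
    "sleepers_under_nets": [5, 2, 2, 4, 3, 0],
})

print("household of 10 with 3 nets ->",
      individual_access_count(10, 3), "people with access")

access = population_access(survey)
hh_access = household_level_access(survey)
use, rate = use_and_rate(survey)
print(f"population access:      {access:.3f}  (people who could sleep 2-per-net)")
print(f"household-level access: {hh_access:.3f}  (households with >= 1 net per 2 people)")
print(f"use:                    {use:.3f}  (slept under a net last night)")
print(f"use rate:               {rate:.3f}  (use among those with access)")
print("-> the individual-level definition is deliberately higher than the "
      "household-level one: partial coverage inside large households counts.")
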