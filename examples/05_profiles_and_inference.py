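"""Mortality profiles and multilevel inference.

Computes proportionate mortality (raw and age-adjusted) for a synthetic
panel, decomposes the variance of simulated life-expectancy draws into
draw/city/country levels, and pools a draw-wise association with
Rubin's rules.
"""

import warnings

import numpy as np
import pandas as pd

from citymort.inference import (
    ModelSpec,
    decompose_variance,
    le_association,
)
from citymort.preprocess import preprocess
from citymort.profiles import profile_table
from citymort.synthetic import make_panel_truths, simulate_deaths

truths = make_panel_truths(2, 4, seed=2, mean_population=200_000)
panel = simulate_deaths(truths, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    clean = preprocess(panel.deaths, seed=11)
    prof = profile_table(clean, panel.census)

print("proportionate mortality (PM) and age-adjusted PM (AAPM):")
first = prof[prof.city_id == truths[0].city_id]
print(first.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("rows per city sum to 1 for both flavors.\n")

# --- variance decomposition of life-expectancy draws ---
# (30 simulated countries: the between-country variance has k-1 degrees
# of freedom, so small panels carry large sampling error on that share)
rng = np.random.default_rng(5)
rows = []
for k in range(30):
    ck = 72 + rng.normal(0, np.sqrt(3.0))          # country level
    for j in range(10):
        cj = ck + rng.normal(0, 1.0)               # city level
        vals = cj + rng.normal(0, np.sqrt(0.5), 200)  # draw level
        rows.append(pd.DataFrame(dict(
            iteration=np.arange(200), city_id=f"{k}-{j}", country_id=f"K{k}",
            life_expectancy=vals, weight=1.0)))
vc = decompose_variance(pd.concat(rows, ignore_index=True))
print("variance decomposition of life-expectancy draws "
      "(simulated components 3 / 1 / 0.5):")
for level, share in vc.proportions.items():
    print(f"  {level:8s} share: {share:.3f}")

# --- draw-wise association pooled by Rubin's rules ---
cities = pd.DataFrame([
    dict(city_id=f"{k}-{j}", country_id=f"K{k}", sei=rng.normal())
    for k in range(6) for j in range(10)
])
ce = {f"K{k}": float(rng.normal(0, 0.7)) for k in range(6)}
frames = []
for it in range(50):
    le = (70 + 0.5 * cities.sei + cities.country_id.map(ce)
          + rng.normal(0, 0.4, len(cities)))
    frames.append(pd.DataFrame(dict(iteration=it, city_id=cities.city_id,
                                    country_id=cities.country_id,
                                    life_expectancy=le)))
pc = le_association(pd.concat(frames, ignore_index=True),
                    cities[["city_id", "sei"]],
                    ModelSpec(predictors=["sei"]))[0]
lo, hi = pc.ci95
print(f"\npooled social-environment-index coefficient (true effect 0.5):")
print(f"  estimate {pc.estimate:.3f}, 95% CI [{lo:.3f}, {hi:.3f}], m={pc.m}")
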