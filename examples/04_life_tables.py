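"""Abridged life tables and life expectancy at reference ages.

Builds a life table from the default female schedule, prints the main
columns, and shows the fixture identities that pin the conventions:
zero mortality before 75 with m(75+) = 0.02 forces e0 = 75 + 1/0.02.
"""

import numpy as np

from citymort.ages import N_AGE
from citymort.lifetables import abridged_life_table, life_expectancy_at
from citymort.synthetic import make_schedule

lt = abridged_life_table(make_schedule(1.0, sex="F").rates, sex="F")
print("abridged life table, default female schedule:")
print(lt.to_frame()[["age_group", "m", "q", "l", "e"]].to_string(
    index=False, float_format=lambda v: f"{v:.5f}"))

print("\nlife expectancy at reference ages:")
for x in (0, 20, 40, 60):
    print(f"  e({x}) = {life_expectancy_at(lt, x):.2f} years")

m = np.zeros(N_AGE)
m[-1] = 0.02
fixture = abridged_life_table(m)
print(f"\nzero mortality before 75, m(75+)=0.02:  e0 = {fixture.e[0]:.1f} "
      "(= 75 survived years + 1/0.02 in the open interval)")

const = abridged_life_table(np.full(N_AGE, 0.02))
print(f"constant hazard m=0.02 at all ages:     e0 = {const.e[0]:.2f} "
      "(continuous-exponential value: 50)")
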