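"""Generate the japan-like synthetic inputs and inspect their shapes.

Builds the Gompertz-Makeham life table, the full-income and full-consumption
profiles, and the aged population pyramid, then prints a few landmark values.
"""

import numpy as np

from vslqaly import SurvivalModel, japan_like
from vslqaly.synthdata import generate_life_table, generate_population, generate_profiles

cfg = japan_like(seed=0)
table = generate_life_table(cfg)
surv = SurvivalModel(table)
profile = generate_profiles(cfg)
pop = generate_population(cfg, total=125_000_000)

print(f"life expectancy at birth : {np.trapezoid(table.lx, table.ages):6.1f} years")
print(f"survival to 65 / 90      : {surv(65, 0):.3f} / {surv(90, 0):.3f}")
print(f"S(80, 65) conditional    : {surv(80, 65):.3f}")
print(f"full income peak         : {profile.full_income.max():.2f} M JPY at age "
      f"{int(profile.ages[np.argmax(profile.full_income)])}")
print(f"full consumption range   : {profile.full_consumption.min():.2f}-"
      f"{profile.full_consumption.max():.2f} M JPY")
print(f"population mean age      : {pop.mean_age:.1f} (total {pop.total:,.0f})")

# The survival curve is the S(t, a) of the lifetime value integrals; the two
# money profiles are its y^F and c^F; the pyramid supplies the N_a weights of
# the policy evaluation.
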