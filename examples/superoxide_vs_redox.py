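"""Superoxide production versus Q-pool redox state with antimycin A bound.

Sweeps the oxidized fraction of a 50 uM decylubiquinone pool for the
antimycin-saturated complex (both Q_n sites blocked, quinol-oxidation
rates reduced by the two inhibition factors) and reports the two
superoxide modes and the location of the peak.
"""

import numpy as np

from bc1dimer import Conditions, default_parameters
from bc1dimer.experiments import scan

p = default_parameters()
cond = Conditions.from_pools(
    q_total=50e-6, q_reduced_fraction=0.5,
    c_total=50e-6, c_reduced_fraction=0.0,
    delta_psi=0.0, O2=250e-6, O2m=100e-12, species="DQ",
)

grid = np.linspace(0.02, 0.98, 49)  # pool reduced fraction
res = scan("q_reduced", grid, cond, p, inhibition="double_AA")
t = res.table

print(f"{'% oxidized':>10s} {'J_SO':>8s} {'semirev':>9s} {'semifwd':>9s}")
for _, row in t.iloc[::6].iterrows():
    print(f"{100 * (1 - row.q_reduced):10.0f} {row.J_SO:8.4f} "
          f"{row.J_SO_sr:9.4f} {row.J_SO_sf:9.4f}")

peak = 100 * (1 - res.argmax_superoxide)
print(f"\ntotal superoxide peaks near {peak:.0f}% oxidized: the "
      "semireverse mode needs quinone at the Q_p site (scarce in a "
      "reduced pool) while the semiforward mode needs quinol and a "
      "fully loaded complex (lost in an oxidized pool)")
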