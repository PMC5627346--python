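"""Antimycin A titration of a dimer population.

Sub-stoichiometric antimycin A leaves a fraction of dimers with exactly
one blocked Q_n site; in those dimers both Q_p sites operate, which
stimulates cytochrome c reduction above the uninhibited rate before
saturating inhibition forces all flux through the superoxide bypass.
"""

import numpy as np

from bc1dimer import Conditions, default_parameters
from bc1dimer.experiments import antimycin_titration, class_fluxes

p = default_parameters()
pct_ox = p.initial_percent_oxidized["covian_trumpower"]
cond = Conditions.from_pools(
    q_total=50e-6, q_reduced_fraction=1 - pct_ox / 100,
    c_total=50e-6, c_reduced_fraction=0.0,
    delta_psi=0.0, O2=250e-6, O2m=100e-12, species="DQ",
)

classes = class_fluxes(cond, p)
jc = {k: v[1].J_c for k, v in classes.items()}
so = {k: v[1].J_SO for k, v in classes.items()}
print("per-dimer class rates (1/s):")
for k in ("none", "single_AA", "double_AA"):
    print(f"  {k:10s} Jc = {jc[k]:7.3f}   J_SO = {so[k]:7.3f}")
print(f"single/none cytochrome c fold: {jc['single_AA'] / jc['none']:.2f}")
print(f"single/none superoxide fold:   {so['single_AA'] / so['none']:.2f}")

table = antimycin_titration(cond, p, np.linspace(0, 1, 51))
i = table["J_c"].idxmax()
print(f"\npopulation maximum: {table.J_c[i] / table.J_c[0]:.3f} x the "
      f"uninhibited rate at {table.aa_ratio[i]:.2f} antimycin/monomer")
print("the singly-bound dimers dominate the binomial mixture at "
      "sub-stoichiometric inhibitor, so the population rate rises before "
      "the doubly-blocked, bypass-only dimers take over")
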