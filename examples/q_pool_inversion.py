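"""Inverting the biphasic flux-redox curve and checking Complex I.

Because cytochrome c reduction is biphasic in the Q-pool redox state, a
measured turnover is compatible with an oxidized-pool and a reduced-pool
solution.  The reduced branch can put Complex I into reverse electron
transport (reaction free energy > 0), which identifies the physiological
branch.
"""

from bc1dimer import Conditions, default_parameters
from bc1dimer.experiments import complex_one_energy, invert_q_redox

p = default_parameters()
cond = Conditions.from_pools(
    q_total=50e-6, q_reduced_fraction=0.5,
    c_total=50e-6, c_reduced_fraction=0.10,
    delta_psi=0.0, O2=250e-6, O2m=100e-12, species="DQ",
)

from bc1dimer.kinetics import steady_state

# pick a target well above the turnover of a half-reduced pool so both
# branches of the sharply biphasic curve cross it
target = round(2.5 * steady_state(cond, p)[1].J_c, 1)
ox = invert_q_redox(target, cond, "oxidized", p, n_grid=41)
red = invert_q_redox(target, cond, "reduced", p, n_grid=41)
print(f"target flux {target} 1/s per dimer:")
for res in (ox, red):
    if res.found:
        print(f"  {res.side:8s} branch: pool {100 * res.q_reduced:.1f}% reduced")
    else:
        print(f"  {res.side:8s} branch: no solution")

print("\nComplex I reaction energy at each solution (NADH pool half "
      "reduced, dpsi 190 mV, no pH gradient):")
for res in (ox, red):
    if not res.found:
        continue
    dg = complex_one_energy(0.5, res.q_reduced, 190.0, 0.0)
    tag = "reverse electron transport" if dg > 0 else "forward"
    print(f"  {res.side:8s} branch: dG = {dg:+7.2f} kJ/mol  ({tag})")
print("positive values mark reverse electron transport, the pathological "
      "regime of extreme free radical production; the more reduced the "
      "solution, the closer Complex I sits to reversal, which is how the "
      "physiological branch is identified")
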