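"""Synthetic calibration data, sensitivity ranking and a small refit.

Generates the four synthetic dataset archetypes (substrate titration,
superoxide vs membrane potential, superoxide vs pool redox with antimycin,
antimycin titration) from the shipped parameters with 5% multiplicative
noise, ranks the local parameter sensitivities, and refits a perturbed
Coulomb energy.
"""

from bc1dimer import default_parameters
from bc1dimer.estimation import (
    FitSettings,
    fit,
    generate_synthetic_datasets,
    get_param,
    local_sensitivities,
    set_param,
)

p = default_parameters()
data = generate_synthetic_datasets(p, noise_fraction=0.05, seed=1)
for ds in data:
    print(f"dataset {ds.name:26s} ({ds.kind:14s}) n = {len(ds.x)}")

sens = local_sensitivities(p, data)
print("\ntop-ranked local sensitivities |(p/J) dJ/dp|:")
print(sens.table.sort_values("rank").head(6).to_string(index=False))

p_start = set_param(p, "dGbHbLCoulomb", 11.6 * 1.5)
res = fit(
    data, ["dGbHbLCoulomb"], p0=p_start, bounds_decades=0.5,
    settings=FitSettings(seed=1, sa_steps=60, local_maxiter=30),
)
fitted = get_param(res.params, "dGbHbLCoulomb")
print(f"\nrefit of the intramonomer Coulomb energy: start 17.4, "
      f"recovered {fitted:.2f} kJ/mol (true 11.6); cost "
      f"{res.trace[0]:.1f} -> {res.best_cost:.1f}")
print("the annealing + local-refinement pipeline recovers a perturbed "
      "parameter from noisy synthetic data with the same seed giving the "
      "same trajectory")
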