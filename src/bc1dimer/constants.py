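"""Physical constants shared across the package.

Energies are carried in kJ/mol throughout, potentials in mV at the API
surface and volts internally, concentrations in mol/L.
"""

# Faraday constant, kJ/(mol.V)
FARADAY = 96.485

# Gas constant, kJ/(mol.K)
GAS_CONSTANT = 8.31446e-3

# Default assay temperature, K
T_DEFAULT = 298.15


def RT(temperature: float = T_DEFAULT) -> float:
    """Thermal energy R*T in kJ/mol."""
    return GAS_CONSTANT * temperature


def nernst_slope_mV(temperature: float = T_DEFAULT) -> float:
    """RT/F in millivolts (~25.69 mV at 298.15 K)."""
    return 1000.0 * RT(temperature) / FARADAY
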