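"""Physical constants and unit conventions.

Internal units throughout the package: length in Angstrom, energy in
kcal/mol, mass in amu, time in fs for integration and ns for analysis.
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: conversion factor: (kcal/mol/Angstrom) / amu -> Angstrom / fs^2
ACCEL_UNIT = 4.184e-4

#: default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol (0.596 kcal/mol at 300 K)."""
    return KB * temperature
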