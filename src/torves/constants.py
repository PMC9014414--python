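"""Physical constants and unit conventions.

Energies are kJ/mol, angles radians, distances nm, temperatures K.
Time is measured in arbitrary "step units" for the surrogate dynamics.
"""

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145

#: Default simulation temperature (K); kT ~ 2.494 kJ/mol.
DEFAULT_TEMPERATURE = 300.0

#: N_A * h * c in kJ nm / mol, for photon-energy conversion.
NA_H_C = 119626.57


def beta(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B T in kJ/mol."""
    return KB * temperature
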