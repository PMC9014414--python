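"""Barrier-to-timescale and wavelength-to-energy conversions.

The Arrhenius/Kramers estimate tau = tau0 * e^{barrier / kT} turns
free-energy barriers into order-of-magnitude interconversion times.
The prefactor tau0 is an explicit assumption -- the default 1 ps is a
typical molecular attempt time -- so only the order of magnitude of
the result is meaningful.  Photon energies convert absorption-band
wavelengths to molar energies, E = N_A h c / lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, NA_H_C, kt

__all__ = ["RateModel", "arrhenius_time", "photon_energy"]


@dataclass(frozen=True)
class RateModel:
    """Attempt-time prefactor (seconds) and temperature (K)."""

    prefactor: float = 1e-12
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def arrhenius_time(barrier: float, model: RateModel = RateModel()) -> float:
    """Thermal crossing time tau0 * e^{barrier/kT} in seconds.

    ``barrier`` is the free-energy barrier in kJ/mol, >= 0.
    """
    if barrier < 0:
        raise ValueError("barrier must be non-negative")
    return model.prefactor * float(np.exp(barrier / kt(model.temperature)))


def photon_energy(wavelength_nm: float) -> float:
    """Molar photon energy N_A h c / lambda in kJ/mol (lambda in nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return NA_H_C / wavelength_nm
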