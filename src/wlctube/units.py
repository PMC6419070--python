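"""Unit system and physical constants.

Internally everything is expressed in nanometres (length), picoseconds
(time) and piconewton-nanometres (energy); 1 pN nm = 1e-21 J = 1 zJ.
Viscosity in these units carries pN ps / nm^2 (1 Pa s = 1e6 pN ps / nm^2).
"""

from __future__ import annotations

import math

#: Boltzmann constant in pN nm / K.
KB = 1.380649e-2

#: Default absolute temperature, K.
DEFAULT_TEMPERATURE = 293.0

#: Default solvent viscosity, Pa s.
DEFAULT_VISCOSITY = 1.005725e-4

#: Conversion factor Pa s -> pN ps / nm^2.
PA_S_TO_INTERNAL = 1.0e6


def kBT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in pN nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def bead_diffusion_coefficient(
    radius: float,
    temperature: float = DEFAULT_TEMPERATURE,
    viscosity: float = DEFAULT_VISCOSITY,
) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere, nm^2 / ps.

    ``radius`` in nm, ``viscosity`` in Pa s.
    """
    if radius <= 0:
        raise ValueError(f"bead radius must be positive, got {radius}")
    eta = viscosity * PA_S_TO_INTERNAL
    return kBT(temperature) / (6.0 * math.pi * eta * radius)


def force_from_fhat(f_hat: float, Lp: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Physical force in pN from the dimensionless tension f^ = fs Lp / kBT."""
    return f_hat * kBT(temperature) / Lp


def fhat_from_force(fs: float, Lp: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dimensionless tension f^ = fs Lp / kBT from a force in pN."""
    return fs * Lp / kBT(temperature)
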