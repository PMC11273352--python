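"""Physical constants used throughout the electrochemistry and energetics code.

All values come from :mod:`scipy.constants` (CODATA). They are bundled in a
single frozen dataclass so that every formula in the package draws on one
consistent set and so tests can assert the defining relations
(``R = k_B * N_A``, ``F = e * N_A``).
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA physical constants (SI units)."""

    gas_constant: float = _sc.R                     # J mol^-1 K^-1
    faraday: float = _sc.physical_constants["Faraday constant"][0]  # C mol^-1
    elementary_charge: float = _sc.e                # C
    vacuum_permittivity: float = _sc.epsilon_0      # F m^-1
    avogadro: float = _sc.N_A                       # mol^-1
    boltzmann: float = _sc.k                        # J K^-1


CONSTANTS = PhysicalConstants()

#: Default bath temperature (K) for a room-temperature free-standing bilayer.
DEFAULT_TEMPERATURE = 296.15
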