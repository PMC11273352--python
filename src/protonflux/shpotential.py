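"""Second-harmonic (SH) intensity -> transmembrane potential conversion and
parallel-plate charge accounting.

A symmetric bilayer produces no coherent SH signal; a transmembrane potential
DeltaPhi_0 orients interfacial water and adds a third-order polarization term,
so the detected intensity follows the quadratic field model

    I = intensity_scale * (chi2_effective + chi3_prime * DeltaPhi_0)^2 .

With chi2_effective = 0 (the symmetric-membrane default) the inversion is
simply DeltaPhi_0 = sqrt(I / intensity_scale) / chi3_prime. Intensity alone
does not carry the sign of DeltaPhi_0, so magnitudes are reported.

The charge accounting treats the membrane as a parallel-plate capacitor of
areal capacitance C = eps0 * eps / d (hydrophobic core: eps = 2.1, d = 4 nm):
a potential drop across one domain maps to a surface charge-density difference
Delta_sigma = C * DeltaPhi, and neutralised charge to a proton count
N = Delta_sigma * A / e.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import CONSTANTS

__all__ = [
    "SHCalibration",
    "CapacitorModel",
    "PotentialMap",
    "ChargeAccounting",
    "potential_from_intensity",
    "intensity_from_potential",
    "capacitance",
    "charge_density_from_potential",
    "bound_protons",
    "interface_retention_fraction",
]

_E = CONSTANTS.elementary_charge
_NA = CONSTANTS.avogadro
_E0 = CONSTANTS.vacuum_permittivity


@dataclass(frozen=True)
class SHCalibration:
    """Calibration of the quadratic SH intensity model.

    ``chi3_prime`` is the effective third-order response per volt,
    ``intensity_scale`` converts squared field amplitude to detector counts,
    and ``chi2_effective`` is the residual second-order amplitude (zero for a
    symmetric membrane). ``reference_potential`` optionally records the anchor
    potential used to fix the product intensity_scale * chi3_prime^2 (e.g.
    from capacitance minimization).
    """

    chi3_prime: float = 1.0
    intensity_scale: float = 4.0e4
    chi2_effective: float = 0.0
    reference_potential: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chi3_prime <= 0 or self.intensity_scale <= 0:
            raise ValueError("chi3_prime and intensity_scale must be > 0")

    @classmethod
    def from_anchor(cls, intensity: float, potential: float,
                    chi2_effective: float = 0.0) -> "SHCalibration":
        """Calibration anchoring one measured intensity to a known potential."""
        if intensity <= 0 or potential <= 0:
            raise ValueError("anchor intensity and potential must be > 0")
        scale = intensity / (chi2_effective + potential) ** 2
        return cls(chi3_prime=1.0, intensity_scale=scale,
                   chi2_effective=chi2_effective, reference_potential=potential)


def intensity_from_potential(delta_phi, cal: SHCalibration = SHCalibration()):
    """Forward SH model: counts produced by potential magnitude ``delta_phi`` (V)."""
    phi = np.asarray(delta_phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("potential magnitudes must be >= 0")
    out = cal.intensity_scale * (cal.chi2_effective + cal.chi3_prime * phi) ** 2
    return float(out) if np.isscalar(delta_phi) else out


def potential_from_intensity(intensity, cal: SHCalibration = SHCalibration()):
    """Invert the quadratic SH model for the potential magnitude (V).

    Works elementwise on arrays. Monotone increasing in intensity; the exact
    inverse of :func:`intensity_from_potential` on DeltaPhi_0 >= 0.
    """
    inten = np.asarray(intensity, dtype=float)
    if np.any(inten < 0):
        raise ValueError("intensity must be >= 0")
    amp = np.sqrt(inten / cal.intensity_scale)
    phi = (amp - cal.chi2_effective) / cal.chi3_prime
    phi = np.maximum(phi, 0.0)
    return float(phi) if np.isscalar(intensity) else phi


@dataclass(frozen=True)
class CapacitorModel:
    """Parallel-plate model of the hydrophobic membrane core."""

    dielectric: float = 2.1
    thickness: float = 4e-9  # m

    def __post_init__(self) -> None:
        if self.dielectric <= 1:
            raise ValueError("dielectric constant must exceed 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")

    @property
    def areal_capacitance(self) -> float:
        """C = eps0 * eps / d (F/m^2)."""
        return _E0 * self.dielectric / self.thickness


def capacitance(eps: float, d: float) -> float:
    """Areal capacitance eps0*eps/d (F/m^2) of a dielectric slab of thickness d (m)."""
    return CapacitorModel(dielectric=eps, thickness=d).areal_capacitance


def charge_density_from_potential(delta_phi: float,
                                  cap: CapacitorModel = CapacitorModel()) -> float:
    """Surface charge-density difference Delta_sigma = C * DeltaPhi (C/m^2)."""
    return cap.areal_capacitance * delta_phi


@dataclass(frozen=True)
class ChargeAccounting:
    """Charge neutralised on one leaflet of a single domain."""

    delta_sigma: float   # C/m^2
    domain_area: float   # m^2
    bound_protons: float  # count (unrounded)
    moles: float         # mol

    def __add__(self, other: "ChargeAccounting") -> "ChargeAccounting":
        area = self.domain_area + other.domain_area
        n = self.bound_protons + other.bound_protons
        sigma = n * _E / area
        return ChargeAccounting(sigma, area, n, n / _NA)


def bound_protons(delta_sigma: float, area: float) -> ChargeAccounting:
    """Protons bound to a leaflet patch: N = Delta_sigma * A / e.

    ``area`` in m^2; the count is kept unrounded (round only when reporting).
    """
    if area <= 0:
        raise ValueError("domain area must be > 0")
    n = delta_sigma * area / _E
    return ChargeAccounting(delta_sigma, area, n, n / _NA)


def interface_retention_fraction(moles_translocated: float, moles_bound: float) -> float:
    """How many protons cross for each one retained at the interface.

    Returns X = moles_translocated / moles_bound, read as "1 out of X remains
    at the membrane interface". Round X to 2 significant figures when printing.
    """
    if moles_translocated <= 0 or moles_bound <= 0:
        raise ValueError("both mole amounts must be > 0")
    return moles_translocated / moles_bound


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class PotentialMap:
    """A per-pixel transmembrane-potential image (V).

    ``pixel_size`` in um, ``timestamp`` in s from acquisition start. Values are
    magnitudes (the SH inversion loses the sign).
    """

    values: np.ndarray
    pixel_size: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential map contains non-finite values")
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("potential magnitudes above 1 V fail the sanity bound")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @classmethod
    def from_intensity(cls, frame: np.ndarray, cal: SHCalibration,
                       pixel_size: float, timestamp: float = 0.0) -> "PotentialMap":
        return cls(potential_from_intensity(frame, cal), pixel_size, timestamp)
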