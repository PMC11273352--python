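"""Water-needle energetics and chain-coordinate-resolved permeability.

Proton translocation across a lipid bilayer proceeds through transient water
needles — thin hydrogen-bonded water columns spanning the hydrophobic core —
rather than fully open pores. Two quantities are computed here:

* The electrostatic stabilization of a water needle by a transmembrane
  potential, modelled as dielectric replacement inside a parallel-plate
  capacitor: filling a cylinder of radius r with water (eps_w) instead of
  membrane (eps_m) in the uniform field U/d lowers the free energy by

      dW = 1/2 eps0 (eps_w - eps_m) (U/d)^2 pi r^2 d,

  quadratic in both U and r, reported in kJ/mol.

* The permeability profile along the chain coordinate xi_ch (0.1 = intact
  membrane, ~0.74 = water needle, 1 = open pore): combining the defect-
  formation free energy dG(xi) with the per-defect proton flux F(xi),

      P(xi) ∝ F(xi) exp(-beta dG(xi)),

  in relative units, plus the "dominant window" — the smallest xi interval
  containing at least 90% of the integrated permeability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, DEFAULT_TEMPERATURE
from .electro import IVRecord, IVFit, fit_iv

__all__ = [
    "NeedleGeometry",
    "DefectProfiles",
    "PermeabilityProfile",
    "needle_stabilization_energy",
    "permeability_profile",
    "needle_conductance",
]

_E0 = CONSTANTS.vacuum_permittivity
_NA = CONSTANTS.avogadro
_R = CONSTANTS.gas_constant


@dataclass(frozen=True)
class NeedleGeometry:
    """Geometry and dielectrics of a cylindrical water needle in the bilayer."""

    radius: float = 3e-10         # m
    thickness: float = 4e-9       # m (hydrophobic core)
    eps_water: float = 80.0
    eps_membrane: float = 2.1

    def __post_init__(self) -> None:
        if not 0 < self.radius < self.thickness:
            raise ValueError("need 0 < radius << membrane thickness")
        if not self.eps_water > self.eps_membrane > 1:
            raise ValueError("need eps_water > eps_membrane > 1")


def needle_stabilization_energy(geom: NeedleGeometry, U: float) -> float:
    """Electrostatic stabilization (kJ/mol) of a water needle at potential U (V).

    Dielectric-replacement energy of a water cylinder spanning the uniform
    field U/d of the membrane capacitor; zero at U = 0 and quadratic in both U
    and the needle radius.
    """
    e_field = U / geom.thickness
    volume = math.pi * geom.radius**2 * geom.thickness
    w = 0.5 * _E0 * (geom.eps_water - geom.eps_membrane) * e_field**2 * volume
    return w * _NA / 1000.0


@dataclass(frozen=True)
class DefectProfiles:
    """Tabulated defect free energy and proton flux along the chain coordinate.

    ``xi`` is dimensionless (typically spanning [0.1, 1]); ``dG`` in kJ/mol
    with dG(xi_min) = 0 by offset convention; ``flux`` in ions/s (>= 0);
    ``voltage`` records the transmembrane potential the profiles refer to.
    """

    xi: np.ndarray
    dG: np.ndarray
    flux: np.ndarray
    voltage: float = 0.3

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=float)
        dg = np.asarray(self.dG, dtype=float)
        fl = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "dG", dg)
        object.__setattr__(self, "flux", fl)
        if not (xi.shape == dg.shape == fl.shape) or xi.ndim != 1 or xi.size < 2:
            raise ValueError("xi, dG and flux must be aligned 1-D arrays with >= 2 points")
        if not np.all(np.diff(xi) > 0):
            raise ValueError("xi grid must be strictly increasing")
        if np.any(fl < 0):
            raise ValueError("flux must be >= 0")


@dataclass(frozen=True)
class PermeabilityProfile:
    """Relative permeability along xi with its integral and dominant window."""

    xi: np.ndarray
    P: np.ndarray
    integral: float
    dominant_window: tuple[float, float]


def _dominant_window(xi: np.ndarray, P: np.ndarray, frac: float = 0.9) -> tuple[float, float]:
    """Smallest [xi_lo, xi_hi] grid interval holding >= ``frac`` of integral P dxi."""
    total = np.trapezoid(P, xi)
    if total <= 0:
        return (float(xi[0]), float(xi[-1]))
    n = xi.size
    best = (float(xi[0]), float(xi[-1]))
    best_width = math.inf
    for i in range(n - 1):
        for j in range(i + 1, n):
            part = np.trapezoid(P[i : j + 1], xi[i : j + 1])
            if part >= frac * total:
                width = xi[j] - xi[i]
                if width < best_width:
                    best_width = width
                    best = (float(xi[i]), float(xi[j]))
                break  # larger j only widens this window
    return best


def permeability_profile(
    profiles: DefectProfiles,
    temperature: float = DEFAULT_TEMPERATURE,
    prefactor: float = 1.0,
) -> PermeabilityProfile:
    """Boltzmann-weighted permeability profile P(xi) = prefactor * F(xi) exp(-beta dG(xi)).

    ``dG`` in kJ/mol, beta = 1/(RT). The profile is in relative units (an
    absolute scale would require an MD-calibrated prefactor); the reported
    integral is trapezoidal over the xi grid, and the dominant window is the
    smallest interval containing >= 90% of it. Adding a constant to dG only
    rescales P globally, leaving the normalized shape and window unchanged.
    """
    beta = 1.0 / (_R * temperature / 1000.0)  # mol/kJ
    P = prefactor * profiles.flux * np.exp(-beta * profiles.dG)
    integral = float(np.trapezoid(P, profiles.xi))
    return PermeabilityProfile(
        xi=profiles.xi.copy(),
        P=P,
        integral=integral,
        dominant_window=_dominant_window(profiles.xi, P),
    )


def needle_conductance(
    iv_per_xi: Sequence[tuple[float, IVRecord]],
) -> tuple[np.ndarray, np.ndarray, list[IVFit], bool]:
    """Linear conductance of water needles of increasing size.

    ``iv_per_xi`` pairs each chain-coordinate value with an I-V record; returns
    (xi array, conductance array (S), fits, monotone_increasing flag).
    """
    if len(iv_per_xi) == 0:
        raise ValueError("need at least one I-V record")
    xi = np.array([x for x, _ in iv_per_xi], dtype=float)
    order = np.argsort(xi)
    fits = [fit_iv(iv_per_xi[k][1]) for k in order]
    G = np.array([f.conductance for f in fits])
    monotone = bool(np.all(np.diff(G) >= 0))
    return xi[order], G, fits, monotone
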