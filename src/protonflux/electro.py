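"""Closed-form membrane electrochemistry.

This module collects the analytic relations used to interpret bilayer
current-voltage (I-V) recordings under a transmembrane pH/KCl gradient:

* the Goldman reversal-potential equation for a two-ion (H+, Cl-) system and
  its inversion for the permeability ratio P_H/P_Cl,
* the Goldman-Hodgkin-Katz (GHK) constant-field flux equation linking a
  single-ion current to its permeability, and its algebraic inversion,
* the flux -> permeability conversion for imaging-derived ion fluxes,
* the unstirred-layer diffusion bound P = D/delta,
* charge-to-moles accounting for zero-bias currents,
* ordinary least-squares I-V fitting (conductance + reversal potential),
* the Gouy-Chapman-Stern (GCS) surface-potential solver via the Grahame
  equation.

Unit conventions follow electrophysiology practice: permeabilities in cm/s,
areas in cm^2, concentrations in mol/L externally (converted to mol/cm^3
internally), voltages in V, currents in A.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import CONSTANTS, DEFAULT_TEMPERATURE

__all__ = [
    "IonConditions",
    "IVRecord",
    "IVFit",
    "PermeabilityResult",
    "GCSParams",
    "proton_concentration",
    "goldman_reversal",
    "permeability_ratio_from_reversal",
    "ghk_current",
    "permeability_from_current",
    "permeability_from_flux",
    "unstirred_layer_permeability",
    "transported_moles",
    "fit_iv",
    "gcs_surface_potential",
    "membrane_disk_area",
]

_R = CONSTANTS.gas_constant
_F = CONSTANTS.faraday
_NA = CONSTANTS.avogadro
_E0 = CONSTANTS.vacuum_permittivity


def proton_concentration(pH: float) -> float:
    """Proton concentration (mol/L) of an ideal solution at the given pH.

    Activities are identified with concentrations: [H+] = 10**(-pH).
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    return 10.0 ** (-pH)


@dataclass(frozen=True)
class IonConditions:
    """Per-compartment bath composition for a free-standing bilayer.

    The *bottom* compartment is the one acidified by HCl addition in the
    experiment emulated here; the *top* compartment stays at the resting pH.
    Concentrations are mol/L, temperature in K.
    """

    pH_bottom: float = 4.1
    pH_top: float = 7.3
    cl_bottom: float = 0.061
    cl_top: float = 0.050
    k_bottom: float = 0.050
    k_top: float = 0.050
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("cl_bottom", "cl_top", "k_bottom", "k_top"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("pH_bottom", "pH_top"):
            if not 0.0 < getattr(self, name) < 14.0:
                raise ValueError(f"{name} must lie in (0, 14)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def h_bottom(self) -> float:
        """[H+] in the bottom compartment (mol/L)."""
        return proton_concentration(self.pH_bottom)

    @property
    def h_top(self) -> float:
        """[H+] in the top compartment (mol/L)."""
        return proton_concentration(self.pH_top)

    @property
    def thermal_voltage(self) -> float:
        """RT/F (V)."""
        return _R * self.temperature / _F


#: Conditions of the acidification experiment: bottom pH dropped 7.3 -> 4.1 by
#: HCl addition (raising its ionic strength to 61 mM), top at pH 7.3, 50 mM KCl.
PAPER_CONDITIONS = IonConditions()


@dataclass(frozen=True)
class IVRecord:
    """One current-voltage sweep (voltages in V, currents in A)."""

    voltages: np.ndarray
    currents: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)
        if v.ndim != 1 or i.shape != v.shape or v.size < 2:
            raise ValueError("voltages and currents must be equal-length 1-D arrays with >= 2 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class IVFit:
    """Least-squares line through an I-V sweep.

    ``conductance`` is the slope G (S); ``reversal_potential`` is the zero-
    current voltage V_m = -intercept/G (V). ``specific_conductance`` (S/cm^2)
    is populated when a membrane area was supplied. ``extrapolated`` flags a
    reversal potential outside the swept range; ``undefined_reversal`` flags a
    flat (G ~ 0) sweep for which V_m is meaningless.
    """

    conductance: float
    reversal_potential: float
    r2: float
    specific_conductance: Optional[float] = None
    extrapolated: bool = False
    undefined_reversal: bool = False
    label: str = ""


@dataclass(frozen=True)
class PermeabilityResult:
    """A membrane permeability (cm/s) together with the route that produced it."""

    value: float
    method: Literal["ghk_current", "sh_flux", "eq4_profile"]
    inputs_digest: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("permeability must be > 0")


def _digest(*items: float | str) -> str:
    h = hashlib.sha256(repr(items).encode())
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Goldman reversal potential and its inversion
# ---------------------------------------------------------------------------

def goldman_reversal(r: float, cond: IonConditions = PAPER_CONDITIONS) -> float:
    """Reversal potential (V) of a H+/Cl- conducting membrane.

    ``r`` is the permeability ratio P_H/P_Cl. The two-ion Goldman equation

        V_m = (RT/F) ln[ (r [H]_bottom + [Cl]_top) / (r [H]_top + [Cl]_bottom) ]

    is oriented so that acid added to the bottom compartment with r > 1 gives
    V_m > 0. At r -> inf it tends to the proton Nernst potential, at r -> 0 to
    the chloride Nernst potential.
    """
    if not r > 0:
        raise ValueError("permeability ratio r must be > 0")
    num = r * cond.h_bottom + cond.cl_top
    den = r * cond.h_top + cond.cl_bottom
    return cond.thermal_voltage * math.log(num / den)


def reversal_limits(cond: IonConditions = PAPER_CONDITIONS) -> tuple[float, float]:
    """Attainable (V_min, V_max) reversal potentials: the Cl- and H+ Nernst limits."""
    v_cl = cond.thermal_voltage * math.log(cond.cl_top / cond.cl_bottom)
    v_h = cond.thermal_voltage * math.log(cond.h_bottom / cond.h_top)
    return (min(v_cl, v_h), max(v_cl, v_h))


def permeability_ratio_from_reversal(
    v_m: float, cond: IonConditions = PAPER_CONDITIONS
) -> float:
    """Invert the Goldman equation for the permeability ratio r = P_H/P_Cl.

    The inversion is algebraic: with E = exp(F V_m / RT),

        r = (E [Cl]_bottom - [Cl]_top) / ([H]_bottom - E [H]_top)

    ``v_m`` must lie strictly between the single-ion Nernst potentials of Cl-
    and H+, otherwise no positive r exists. Symmetric baths make every r a
    solution; that ill-posed case raises as well.
    """
    if math.isclose(cond.h_bottom, cond.h_top) and math.isclose(cond.cl_bottom, cond.cl_top):
        raise ValueError("symmetric conditions: reversal potential carries no ratio information")
    lo, hi = reversal_limits(cond)
    if not lo < v_m < hi:
        raise ValueError(
            f"V_m = {v_m:.4g} V outside the attainable interval ({lo:.4g}, {hi:.4g}) V; "
            "no permeability ratio reproduces it"
        )
    e_fac = math.exp(v_m / cond.thermal_voltage)
    r = (e_fac * cond.cl_bottom - cond.cl_top) / (cond.h_bottom - e_fac * cond.h_top)
    if r <= 0:
        raise ValueError("no positive permeability ratio solves the Goldman equation here")
    return r


# ---------------------------------------------------------------------------
# GHK flux equation
# ---------------------------------------------------------------------------

def _ghk_scale(P: float, U: float, cond: IonConditions, area: float, z: int,
               inside: str) -> float:
    """Current (A) predicted by the GHK flux equation for the proton.

    ``inside`` selects which compartment plays the role of the intracellular
    side in the constant-field expression; the top (resting pH) compartment is
    the default. Concentrations are converted to mol/cm^3 so that P in cm/s and
    area in cm^2 yield amperes.
    """
    if inside == "top":
        c_in, c_out = cond.h_top * 1e-3, cond.h_bottom * 1e-3
    elif inside == "bottom":
        c_in, c_out = cond.h_bottom * 1e-3, cond.h_top * 1e-3
    else:
        raise ValueError("inside must be 'top' or 'bottom'")
    rt = _R * cond.temperature
    u = z * _F * U / rt
    if abs(u) < 1e-9:
        # series limit: i -> P z F A [ (c_in - c_out) + u (c_in + c_out)/2 ]
        return P * z * _F * area * ((c_in - c_out) + u * (c_in + c_out) / 2.0)
    ratio = (c_in - c_out * math.exp(-u)) / (-math.expm1(-u))
    return P * z**2 * _F**2 * U * area / rt * ratio


def ghk_current(
    P: float,
    U: float,
    cond: IonConditions = PAPER_CONDITIONS,
    area: float = 9503e-8,
    z: int = 1,
    inside: str = "top",
) -> float:
    """GHK constant-field current (A) for permeability ``P`` (cm/s) at bias ``U`` (V).

    ``area`` is the membrane area in cm^2 (default: the 55 um radius aperture,
    9503 um^2). The U -> 0 limit is handled analytically and reduces to the
    Ohmic conductance G = P z^2 F^2 C A / (RT) for symmetric concentrations.
    The expression is antisymmetric under swapping compartments together with
    the sign of U.
    """
    if not P > 0:
        raise ValueError("permeability must be > 0")
    if not area > 0:
        raise ValueError("area must be > 0")
    return _ghk_scale(P, U, cond, area, z, inside)


def permeability_from_current(
    i: float,
    U: float,
    cond: IonConditions = PAPER_CONDITIONS,
    area: float = 9503e-8,
    z: int = 1,
    inside: str = "top",
) -> PermeabilityResult:
    """Invert the GHK current equation for the proton permeability (cm/s).

    The GHK current is linear in P, so the inversion is exact:
    P = i / i(P=1). Raises if the measured current opposes the direction a
    passive proton flow would take at this bias (sign mismatch against the
    top-side-as-inside convention).
    """
    if i == 0 or U == 0:
        raise ValueError("current and bias must be nonzero to infer a permeability")
    unit = _ghk_scale(1.0, U, cond, area, z, inside)
    P = i / unit
    if P <= 0:
        raise ValueError(
            "current/bias sign combination is inconsistent with passive flow under the "
            f"'{inside}'-compartment-as-inside convention"
        )
    return PermeabilityResult(P, "ghk_current", _digest(i, U, area, z, inside))


def permeability_from_flux(flux: float, area: float, delta_c: float) -> PermeabilityResult:
    """Permeability (cm/s) from an imaging-derived ion flux.

    P = flux / (N_A * area * delta_c) with ``flux`` in ions/s, ``area`` in cm^2
    and ``delta_c`` the driving concentration difference in mol/cm^3.
    """
    if flux <= 0 or area <= 0:
        raise ValueError("flux and area must be > 0")
    if delta_c <= 0:
        raise ValueError("concentration gradient must be > 0 (zero gradient drives no flux)")
    P = flux / (_NA * area * delta_c)
    return PermeabilityResult(P, "sh_flux", _digest(flux, area, delta_c))


def unstirred_layer_permeability(D: float, delta: float) -> float:
    """Diffusion-limited permeability D/delta (cm/s) of an unstirred layer.

    ``D`` is the diffusion coefficient of the proton carrier (cm^2/s) and
    ``delta`` the layer thickness (cm). This bounds the permeability a bilayer
    measurement can resolve.
    """
    if D < 0 or delta <= 0:
        raise ValueError("D must be >= 0 and delta > 0")
    return D / delta


def transported_moles(
    current: float | Sequence[float],
    duration: float | None = None,
    times: Sequence[float] | None = None,
) -> float:
    """Moles of monovalent charge carried by a zero-bias current.

    Either a constant ``current`` (A) with a ``duration`` (s), or a sampled
    trace (``current`` array with matching ``times``) integrated trapezoidally.
    Returns |Q|/F in moles.
    """
    if times is not None:
        i = np.abs(np.asarray(current, dtype=float))
        t = np.asarray(times, dtype=float)
        if i.shape != t.shape or i.ndim != 1 or i.size < 2:
            raise ValueError("trace integration needs matching 1-D current and time arrays")
        charge = float(np.trapezoid(i, t))
    else:
        if duration is None or duration <= 0:
            raise ValueError("duration must be > 0 for a constant current")
        charge = abs(float(current)) * duration
    return charge / _F


def membrane_disk_area(radius_um: float) -> float:
    """Area (um^2) of a circular membrane aperture of the given radius (um)."""
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    return math.pi * radius_um**2


# ---------------------------------------------------------------------------
# I-V fitting
# ---------------------------------------------------------------------------

def fit_iv(iv: IVRecord, area: Optional[float] = None) -> IVFit:
    """Ordinary least-squares line through an I-V sweep.

    Slope -> conductance G (S); x-intercept -> reversal potential V_m.
    ``area`` (cm^2), when given, populates the specific conductance G/area.
    A sweep with negligible slope relative to its current scatter (or exactly
    zero) gets ``undefined_reversal``; a V_m outside the swept range is
    flagged ``extrapolated``.
    """
    v, i = iv.voltages, iv.currents
    if np.ptp(v) == 0:
        raise ValueError("all voltages equal: I-V slope is undefined")
    slope, intercept = np.polyfit(v, i, 1)
    pred = slope * v + intercept
    ss_res = float(np.sum((i - pred) ** 2))
    ss_tot = float(np.sum((i - np.mean(i)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    undefined = slope == 0 or (ss_tot == 0 and np.allclose(i, 0))
    if undefined:
        vm, extrap = math.nan, False
    else:
        vm = -intercept / slope
        extrap = not (v.min() <= vm <= v.max())
    spec = slope / area if area else None
    return IVFit(
        conductance=float(slope),
        reversal_potential=vm,
        r2=r2,
        specific_conductance=spec,
        extrapolated=extrap,
        undefined_reversal=bool(undefined),
        label=iv.label,
    )


# ---------------------------------------------------------------------------
# Gouy-Chapman-Stern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCSParams:
    """Parameters of the Gouy-Chapman-Stern double-layer model.

    ``ionic_strength`` in mol/L (1:1 electrolyte), ``stern_capacitance`` in
    F/m^2 (omit for pure Gouy-Chapman), temperature in K.
    """

    ionic_strength: float = 0.060
    relative_permittivity_water: float = 80.0
    stern_capacitance: Optional[float] = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.ionic_strength <= 0:
            raise ValueError("ionic_strength must be > 0")
        if self.relative_permittivity_water <= 1:
            raise ValueError("relative_permittivity_water must exceed 1")
        if self.stern_capacitance is not None and self.stern_capacitance <= 0:
            raise ValueError("stern_capacitance must be > 0 when given")

    @property
    def debye_kappa(self) -> float:
        """Inverse Debye length (1/m) of the 1:1 electrolyte."""
        c = self.ionic_strength * 1e3  # mol/m^3
        rt = _R * self.temperature
        return math.sqrt(2 * _F**2 * c / (_E0 * self.relative_permittivity_water * rt))


def gcs_surface_potential(sigma: float, p: GCSParams = GCSParams()) -> float:
    """Surface potential (V) at areal charge density ``sigma`` (C/m^2).

    The diffuse-layer potential solves the Grahame equation

        sigma = sqrt(8 eps0 eps_w R T c) sinh(F psi_d / 2RT),

    inverted in closed form with asinh. When a Stern capacitance is set, the
    condensed-layer drop sigma/C_stern is added, so the total surface potential
    exceeds the pure diffuse-layer value for any sigma != 0. Odd and strictly
    increasing in sigma.
    """
    c = p.ionic_strength * 1e3  # mol/m^3
    rt = _R * p.temperature
    pref = math.sqrt(8 * _E0 * p.relative_permittivity_water * rt * c)
    psi = 2 * rt / _F * math.asinh(sigma / pref)
    if p.stern_capacitance is not None:
        psi += sigma / p.stern_capacitance
    return psi


def gcs_charge_for_potential(psi: float, p: GCSParams = GCSParams()) -> float:
    """Invert :func:`gcs_surface_potential`: charge density (C/m^2) producing ``psi``.

    Root-found on the monotone forward model; used to ask how much lipid charge
    a given surface potential requires with and without a Stern layer.
    """
    if psi == 0:
        return 0.0
    f = lambda s: gcs_surface_potential(s, p) - psi
    hi = math.copysign(1e-6, psi)
    while f(hi) * psi < 0:  # expand until bracketed
        hi *= 10
        if abs(hi) > 1e6:
            raise RuntimeError("failed to bracket the Grahame inversion")
    return brentq(f, 0 if psi > 0 else hi, hi if psi > 0 else 0, xtol=1e-18, rtol=1e-14)
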