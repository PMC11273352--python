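"""Closed-form electrochemistry: Goldman, GHK, I-V fitting, GCS."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from protonflux import (
    CONSTANTS,
    GCSParams,
    IonConditions,
    IVRecord,
    fit_iv,
    gcs_surface_potential,
    ghk_current,
    goldman_reversal,
    membrane_disk_area,
    permeability_from_current,
    permeability_from_flux,
    permeability_ratio_from_reversal,
    proton_concentration,
    transported_moles,
    unstirred_layer_permeability,
)
from protonflux.electro import gcs_charge_for_potential, reversal_limits

AREA_CM2 = 9503e-8


def test_constants_defining_relations():
    assert CONSTANTS.gas_constant == pytest.approx(
        CONSTANTS.boltzmann * CONSTANTS.avogadro, rel=1e-6)
    assert CONSTANTS.faraday == pytest.approx(
        CONSTANTS.elementary_charge * CONSTANTS.avogadro, rel=1e-6)


@pytest.mark.parametrize("pH, expected", [
    (7.0, 1.0e-7),
    (4.1, 7.943e-5),
    (7.3, 5.012e-8),
])
def test_proton_concentration(pH, expected):
    assert proton_concentration(pH) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize("pH", [0.0, 14.0, -1.0, 15.0])
def test_proton_concentration_domain(pH):
    with pytest.raises(ValueError):
        proton_concentration(pH)


class TestGoldman:
    def test_symmetric_conditions_zero(self):
        cond = IonConditions(pH_bottom=7.3, pH_top=7.3, cl_bottom=0.05, cl_top=0.05)
        for r in (0.01, 1.0, 1e4):
            assert goldman_reversal(r, cond) == pytest.approx(0.0, abs=1e-15)

    def test_nernst_limit(self, paper_conditions):
        """r -> inf tends to the proton Nernst potential (RT/F) ln(10^3.2)."""
        nernst = paper_conditions.thermal_voltage * math.log(10 ** 3.2)
        assert nernst == pytest.approx(0.188, abs=5e-4)
        assert goldman_reversal(1e12, paper_conditions) == pytest.approx(nernst, rel=1e-3)

    def test_printed_reversal_scale(self, paper_conditions):
        """A ratio in the several-hundred range puts V_m at ~15 mV."""
        assert goldman_reversal(748, paper_conditions) == pytest.approx(0.015, abs=1e-3)

    def test_monotone_in_r(self, paper_conditions):
        rs = np.logspace(-3, 6, 200)
        vs = [goldman_reversal(r, paper_conditions) for r in rs]
        assert np.all(np.diff(vs) > 0)


class TestRatioInversion:
    def test_paper_bound(self, paper_conditions):
        """V_m = 15 mV implies H+ conducted >50-fold better than Cl-."""
        assert permeability_ratio_from_reversal(0.015, paper_conditions) > 50

    def test_two_mv_still_above_bound(self, paper_conditions):
        r = permeability_ratio_from_reversal(0.002, paper_conditions)
        assert r == pytest.approx(201.22, rel=1e-3)
        assert r > 50

    @pytest.mark.parametrize("v_m", [0.002, 0.005, 0.015, 0.05, 0.15])
    def test_matches_bisection_oracle(self, v_m, paper_conditions):
        """Closed-form inversion agrees with root-finding on the forward model."""
        oracle = brentq(
            lambda r: goldman_reversal(r, paper_conditions) - v_m,
            1e-6, 1e12, xtol=1e-300, rtol=8.9e-16,
        )
        assert permeability_ratio_from_reversal(v_m, paper_conditions) == pytest.approx(
            oracle, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-3, max_value=6))
    def test_round_trip(self, log_r):
        r = 10.0 ** log_r
        cond = IonConditions()
        v = goldman_reversal(r, cond)
        assert permeability_ratio_from_reversal(v, cond) == pytest.approx(r, rel=1e-9)

    def test_symmetric_ill_posed(self):
        cond = IonConditions(pH_bottom=7.3, pH_top=7.3, cl_bottom=0.05, cl_top=0.05)
        with pytest.raises(ValueError):
            permeability_ratio_from_reversal(0.0, cond)

    def test_outside_attainable_interval(self, paper_conditions):
        lo, hi = reversal_limits(paper_conditions)
        with pytest.raises(ValueError):
            permeability_ratio_from_reversal(hi + 0.01, paper_conditions)
        with pytest.raises(ValueError):
            permeability_ratio_from_reversal(lo - 0.01, paper_conditions)


class TestGHK:
    def test_ohmic_limit_symmetric(self):
        """Small-U current approaches G*U with G = P z^2 F^2 C A / (RT)."""
        cond = IonConditions(pH_bottom=5.0, pH_top=5.0)
        P, U = 1e-5, 1e-6
        c = proton_concentration(5.0) * 1e-3  # mol/cm^3
        G = (P * CONSTANTS.faraday**2 * c * AREA_CM2
             / (CONSTANTS.gas_constant * cond.temperature))
        assert ghk_current(P, U, cond, AREA_CM2) == pytest.approx(G * U, rel=1e-5)

    def test_zero_bias_ficks_law(self, paper_conditions):
        """At U = 0 the GHK current reduces to Fickian diffusion z F A P (c_in - c_out)."""
        P = 3.7e-6
        c_in = paper_conditions.h_top * 1e-3
        c_out = paper_conditions.h_bottom * 1e-3
        expected = P * CONSTANTS.faraday * AREA_CM2 * (c_in - c_out)
        assert ghk_current(P, 0.0, paper_conditions, AREA_CM2) == pytest.approx(
            expected, rel=1e-6)

    def test_printed_current_scale(self, paper_conditions):
        """P = 3.7e-6 cm/s at -60 mV reproduces the printed few-pA proton current."""
        i = ghk_current(3.7e-6, -0.06, paper_conditions, AREA_CM2)
        assert i == pytest.approx(-7.6e-12, rel=0.15)

    def test_linearity_in_P(self, paper_conditions):
        i1 = ghk_current(1e-6, -0.03, paper_conditions, AREA_CM2)
        i2 = ghk_current(2e-6, -0.03, paper_conditions, AREA_CM2)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_antisymmetry_under_swap(self, paper_conditions):
        i_top = ghk_current(2e-6, 0.04, paper_conditions, AREA_CM2, inside="top")
        i_bot = ghk_current(2e-6, -0.04, paper_conditions, AREA_CM2, inside="bottom")
        assert i_top == pytest.approx(-i_bot, rel=1e-12)

    def test_permeability_from_printed_current(self, paper_conditions):
        """(-7.6 pA, -60 mV, 9503 um^2) inverts to ~3.7e-6 cm/s."""
        res = permeability_from_current(-7.6e-12, -0.06, paper_conditions, AREA_CM2)
        assert res.value == pytest.approx(3.7e-6, rel=0.15)
        assert res.method == "ghk_current"

    def test_second_membrane_current_inverts(self, paper_conditions):
        res = permeability_from_current(-4.6e-12, -0.06, paper_conditions, AREA_CM2)
        assert res.value == pytest.approx(2.4306e-6, rel=1e-3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.floats(min_value=-8, max_value=-4),
        st.floats(min_value=-0.1, max_value=0.1).filter(lambda u: abs(u) > 1e-4),
    )
    def test_round_trip(self, log_p, u):
        P = 10.0 ** log_p
        cond = IonConditions()
        i = ghk_current(P, u, cond, AREA_CM2)
        assert permeability_from_current(i, u, cond, AREA_CM2).value == pytest.approx(
            P, rel=1e-9)

    def test_sign_mismatch_raises(self, paper_conditions):
        with pytest.raises(ValueError, match="convention"):
            permeability_from_current(+7.6e-12, -0.06, paper_conditions, AREA_CM2)


class TestFluxPermeability:
    def test_printed_values(self, paper_conditions):
        """Imaging fluxes of 7.5e6 / 0.8e6 ions/s give the printed permeabilities."""
        delta_c = (paper_conditions.h_bottom - paper_conditions.h_top) * 1e-3
        assert permeability_from_flux(7.5e6, AREA_CM2, delta_c).value == pytest.approx(
            1.7e-6, rel=0.10)
        assert permeability_from_flux(0.8e6, AREA_CM2, delta_c).value == pytest.approx(
            0.2e-6, rel=0.15)

    def test_linearity(self):
        a = permeability_from_flux(1e6, AREA_CM2, 1e-8).value
        b = permeability_from_flux(2e6, AREA_CM2, 1e-8).value
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_gradient_raises(self):
        with pytest.raises(ValueError, match="gradient"):
            permeability_from_flux(1e6, AREA_CM2, 0.0)


def test_unstirred_layer_bound():
    assert unstirred_layer_permeability(5e-6, 200e-4) == pytest.approx(2.5e-4, rel=1e-12)
    assert unstirred_layer_permeability(5e-6, 1e12) == pytest.approx(0.0, abs=1e-15)
    assert unstirred_layer_permeability(0.0, 0.02) == 0.0


class TestTransportedMoles:
    def test_single_ion(self):
        one_ion = transported_moles(CONSTANTS.elementary_charge, 1.0)
        assert one_ion == pytest.approx(1.0 / CONSTANTS.avogadro, rel=1e-9)

    def test_hour_of_zero_bias_current(self):
        """~1.53 pA sustained for 1 h carries ~5.7e-14 mol of protons."""
        assert transported_moles(1.5277e-12, 3600.0) == pytest.approx(5.7e-14, rel=1e-3)

    def test_trace_integration_matches_constant(self):
        t = np.linspace(0, 3600, 100)
        i = np.full_like(t, 2.0e-12)
        assert transported_moles(i, times=t) == pytest.approx(
            transported_moles(2.0e-12, 3600.0), rel=1e-12)

    def test_zero_current(self):
        assert transported_moles(0.0, 100.0) == 0.0


def test_membrane_disk_area():
    assert round(membrane_disk_area(55.0)) == 9503


class TestFitIV:
    def test_exact_line_recovery(self):
        v = np.linspace(-0.06, 0.06, 11)
        iv = IVRecord(v, 2e-10 * (v - 0.015))
        fit = fit_iv(iv, area=AREA_CM2)
        assert fit.conductance == pytest.approx(2e-10, rel=1e-12)
        assert fit.reversal_potential == pytest.approx(0.015, rel=1e-9)
        assert fit.specific_conductance == pytest.approx(2e-10 / AREA_CM2, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_reversal_within_three_sigma(self):
        """Monte-Carlo: V_rev estimates stay within 3x their propagated error."""
        g_true, vr_true = 1e-10, 0.015
        v = np.linspace(-0.06, 0.06, 11)
        sigma = 0.02 * np.ptp(g_true * (v - vr_true))
        misses = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            i = g_true * (v - vr_true) + rng.normal(0, sigma, v.size)
            (a, b), cov = np.polyfit(v, i, 1, cov=True)
            vr = -b / a
            var = (vr**2) * (cov[0, 0] / a**2 + cov[1, 1] / b**2 - 2 * cov[0, 1] / (a * b))
            if abs(vr - vr_true) > 3 * math.sqrt(max(var, 0)):
                misses += 1
            fit = fit_iv(IVRecord(v, i))
            assert fit.reversal_potential == pytest.approx(vr, rel=1e-9)
        assert misses <= 2  # ~0.3% expected per draw

    def test_flat_zero_current(self):
        v = np.linspace(-0.05, 0.05, 7)
        fit = fit_iv(IVRecord(v, np.zeros_like(v)))
        assert fit.conductance == 0.0
        assert fit.undefined_reversal
        assert math.isnan(fit.reversal_potential)

    def test_non_increasing_voltages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            IVRecord(np.array([0.0, 0.0, 0.01]), np.zeros(3))


class TestGCS:
    def test_zero_charge_zero_potential(self):
        assert gcs_surface_potential(0.0) == 0.0

    def test_odd_and_monotone(self):
        p = GCSParams()
        sigmas = np.linspace(-0.3, 0.3, 31)
        psis = [gcs_surface_potential(s, p) for s in sigmas]
        assert np.all(np.diff(psis) > 0)
        for s in (0.01, 0.1, 0.25):
            assert gcs_surface_potential(-s, p) == pytest.approx(
                -gcs_surface_potential(s, p), rel=1e-12)

    def test_stern_layer_enables_high_potentials(self):
        """350 mV at 60 mM needs implausible lipid charge without a Stern layer."""
        no_stern = GCSParams(ionic_strength=0.060)
        with_stern = GCSParams(ionic_strength=0.060, stern_capacitance=1.0)
        for s in (0.05, 0.2, 0.5):
            assert gcs_surface_potential(s, with_stern) > gcs_surface_potential(s, no_stern)
        sigma_needed = gcs_charge_for_potential(0.35, no_stern)
        assert sigma_needed > 5.0  # C/m^2: far beyond any lipid monolayer
        sigma_stern = gcs_charge_for_potential(0.35, with_stern)
        assert sigma_stern < 0.5

    def test_linearized_debye_limit(self):
        """Grahame matches the Debye-Huckel closed form to 1% below 10 mV."""
        kappa = GCSParams().debye_kappa
        eps = CONSTANTS.vacuum_permittivity * GCSParams().relative_permittivity_water
        for stern in (None, 1.0):
            p = GCSParams(stern_capacitance=stern)
            for sigma in (5e-4, 2e-3, 5e-3):
                linear = sigma / (eps * kappa) + (sigma / stern if stern else 0.0)
                psi = gcs_surface_potential(sigma, p)
                assert abs(psi) < 0.010 or stern is not None
                assert psi == pytest.approx(linear, rel=0.01)

    def test_charge_potential_round_trip(self):
        p = GCSParams(stern_capacitance=1.0)
        for psi in (-0.3, -0.05, 0.02, 0.35):
            s = gcs_charge_for_potential(psi, p)
            assert gcs_surface_potential(s, p) == pytest.approx(psi, rel=1e-9)
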