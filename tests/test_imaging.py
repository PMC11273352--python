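"""Segmentation, occurrence histograms, decay fitting, tau/flux maps."""
import numpy as np
import pytest

from protonflux import (
    SHCalibration,
    domain_occurrence_histogram,
    fit_exponential_decay,
    intensity_from_potential,
    mean_domain_potential_series,
    roi_tau_map,
    segment_domains,
    tau_to_flux,
)
from protonflux.imaging import DEFAULT_TAU_FLUX_K, DomainRecord
from protonflux.synthetic import _render_disk


def _blob_frame(rng, centers, radius=3.0, value=600.0, shape=(100, 100), background=20.0):
    frame = np.zeros(shape)
    for r, c in centers:
        _render_disk(frame, r, c, radius, value)
    return frame + background + rng.normal(0, 3.0, shape)


class TestSegmentation:
    def test_pure_noise_has_no_domains(self, rng):
        frame = 20.0 + rng.normal(0, 3.0, (100, 100))
        assert segment_domains(frame, pixel_size=0.45) == []

    def test_twelve_blobs_recovered_with_subpixel_centroids(self, rng):
        centers = [(10 + 25 * i, 12 + 20 * j) for i in range(4) for j in range(3)]
        frame = _blob_frame(rng, centers)
        domains = segment_domains(frame, pixel_size=0.45)
        assert len(domains) == 12
        found = sorted(d.centroid for d in domains)
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) < 1.0 and abs(fc - tc) < 1.0

    def test_small_blob_excluded_by_min_area(self, rng):
        frame = _blob_frame(rng, [(50, 50)], radius=0.8)  # ~2 px
        assert segment_domains(frame, pixel_size=0.45, min_area=4 * 0.45**2) == []

    def test_constant_frame_yields_nothing(self):
        assert segment_domains(np.full((50, 50), 7.0), pixel_size=0.45) == []

    def test_intensity_rescaling_equivariance(self, rng):
        """Relative thresholding: scaling the frame leaves the segmentation unchanged."""
        frame = _blob_frame(rng, [(30, 30), (70, 60)])
        a = segment_domains(frame, pixel_size=0.45)
        b = segment_domains(frame * 3.0, pixel_size=0.45)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert da.centroid == pytest.approx(db.centroid)
            assert da.area_um2 == pytest.approx(db.area_um2)


def _records(potentials):
    return [
        DomainRecord(frame=0, coords=np.zeros((4, 2)), centroid=(0, 0),
                     area_um2=1.0, mean_intensity=1.0, mean_potential=p)
        for p in potentials
    ]


class TestOccurrenceHistogram:
    def test_gaussian_recovery_at_500_domains(self, rng):
        pots = rng.normal(0.12, 0.05, 500)
        hist = domain_occurrence_histogram(_records(pots))
        assert hist.reliable
        assert hist.gaussian_mu == pytest.approx(0.12, abs=0.007)
        assert hist.gaussian_sigma == pytest.approx(0.05, abs=0.007)

    def test_translation_equivariance(self, rng):
        pots = rng.normal(0.10, 0.03, 400)
        h0 = domain_occurrence_histogram(_records(pots))
        h1 = domain_occurrence_histogram(_records(pots + 0.05))
        assert h1.gaussian_mu - h0.gaussian_mu == pytest.approx(0.05, abs=0.004)

    def test_degenerate_single_value_flagged(self):
        hist = domain_occurrence_histogram(_records([0.1] * 10))
        assert not hist.reliable
        assert hist.gaussian_sigma == 0.0

    def test_too_few_domains_flagged(self):
        assert not domain_occurrence_histogram(_records([0.1, 0.12, 0.13])).reliable


class TestDecayFit:
    @pytest.mark.parametrize("tau", [67.0, 442.0])
    def test_exact_exponential_recovery(self, tau):
        """The two whole-membrane decay constants are recovered to <0.1%."""
        t = np.linspace(0, 300, 80)
        y = 0.2 * np.exp(-t / tau) + 0.01
        fit = fit_exponential_decay(t, y, t_start=0.0)
        assert fit.tau == pytest.approx(tau, rel=1e-3)
        assert not fit.flagged

    def test_intensity_scale_accounts_for_quadratic_signal(self):
        """Intensity decays at tau/2; the fit still reports the potential tau."""
        tau = 42.0
        t = np.linspace(0, 200, 60)
        y = 500.0 * np.exp(-2 * t / tau) + 20.0
        fit = fit_exponential_decay(t, y, t_start=0.0, scale="intensity")
        assert fit.tau == pytest.approx(tau, rel=1e-3)

    def test_constant_series_flagged(self):
        t = np.linspace(0, 100, 20)
        fit = fit_exponential_decay(t, np.full_like(t, 3.0), t_start=0.0)
        assert fit.flagged

    def test_auto_t_start_after_peak(self):
        t = np.linspace(0, 120, 60)
        rise = np.clip(t / 20.0, 0, 1)
        y = 0.3 * rise * np.exp(-np.maximum(t - 20.0, 0) / 50.0)
        fit = fit_exponential_decay(t, y)
        assert fit.t_start == pytest.approx(20.0, abs=5.0)
        assert fit.tau == pytest.approx(50.0, rel=0.05)


class TestTauToFlux:
    def test_anchor_pair(self):
        assert tau_to_flux(67.0) == pytest.approx(7.5e6, rel=1e-12)

    def test_mean_roi_tau_maps_to_printed_flux(self):
        assert tau_to_flux(42.0) == pytest.approx(1.1964e7, rel=1e-4)

    def test_product_invariant(self):
        for tau in (5.0, 42.0, 442.0):
            assert tau_to_flux(tau) * tau == pytest.approx(DEFAULT_TAU_FLUX_K, rel=1e-12)


class TestRoiTauMap:
    def _uniform_tau_stack(self, tau=40.0, shape=(60, 30, 30), period_min=4.0):
        t = np.arange(shape[0]) * period_min
        env2 = np.exp(-2 * t / tau)
        stack = 400.0 * env2[:, None, None] * np.ones(shape) + 20.0
        return stack, t

    def test_uniform_field_recovered(self):
        stack, t = self._uniform_tau_stack()
        tmap = roi_tau_map(stack, t, pixel_size=0.45, roi_size=4.5, t_start=0.0, window=1)
        assert np.all(np.isfinite(tmap.tau))
        assert tmap.tau == pytest.approx(40.0, rel=0.01)
        assert tmap.flux == pytest.approx(DEFAULT_TAU_FLUX_K / 40.0, rel=0.01)

    def test_single_roi_equals_whole_field(self):
        stack, t = self._uniform_tau_stack()
        big = roi_tau_map(stack, t, pixel_size=0.45, roi_size=1e4, t_start=0.0, window=1)
        assert big.tau.shape == (1, 1)
        assert big.tau[0, 0] == pytest.approx(40.0, rel=0.01)

    def test_dead_roi_is_missing_not_zero(self):
        stack, t = self._uniform_tau_stack(shape=(60, 20, 20))
        stack[:, :10, :10] = 20.0  # no signal in one quadrant
        tmap = roi_tau_map(stack, t, pixel_size=0.45, roi_size=4.5, t_start=0.0, window=1)
        assert np.isnan(tmap.tau[0, 0])
        assert np.isfinite(tmap.tau[1, 1])


class TestMeanDomainPotentialSeries:
    def test_series_peaks_at_envelope_peak(self, small_stack, small_spec):
        stack, gt = small_stack
        starts, series = mean_domain_potential_series(
            stack, small_spec.pixel_size, small_spec.calibration, window=20)
        t_min = starts * small_spec.frame_period / 60.0
        peak_window = np.nanargmax(series)
        t_peak = small_spec.t_add + small_spec.rise_time
        assert abs(t_min[peak_window] - t_peak) <= 12.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            mean_domain_potential_series(np.zeros((1, 8, 8)), 0.45, SHCalibration())
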