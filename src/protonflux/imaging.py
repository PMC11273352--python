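"""Time-lapse SH image analysis: domain segmentation, potential histograms,
and decay-constant (tau) mapping.

The analysis chain mirrors how bright transient domains in SH images of a
planar bilayer are quantified:

1.  Per frame, domains are segmented by robust thresholding (background median
    plus ``k_sigma`` robust standard deviations) followed by 4-connected
    component labelling and a minimum-area filter.
2.  Per-domain mean potentials (via the SH calibration) are pooled over a
    window of frames (20 by default) into an occurrence histogram with a
    Gaussian least-squares fit reporting (mu, sigma).
3.  The global rise-then-decay envelope of the signal after acidification is
    fitted with a single exponential on its decaying part, yielding a decay
    constant tau per region of interest (ROI). SH intensity scales with the
    *square* of the transmembrane potential, so intensity traces are fitted
    with exp(-2 t / tau) and tau always refers to the potential decay.
4.  tau converts to an ion flux through the membrane patch by inverse
    proportionality, anchored to a reference (tau, flux) pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage import measure

from .shpotential import SHCalibration, potential_from_intensity

__all__ = [
    "DomainRecord",
    "DomainHistogram",
    "DecayFit",
    "TauMap",
    "segment_domains",
    "domain_occurrence_histogram",
    "mean_domain_potential_series",
    "fit_exponential_decay",
    "roi_tau_map",
    "tau_to_flux",
    "DEFAULT_TAU_FLUX_K",
]

#: Anchor for the tau -> flux conversion: a whole-membrane decay constant of
#: 67 min corresponds to a flux of 7.5e6 ions/s, giving K = flux * tau.
DEFAULT_TAU_FLUX_K = 67.0 * 7.5e6  # ions * min / s


@dataclass(frozen=True)
class DomainRecord:
    """One segmented SH domain in one frame."""

    frame: int
    coords: np.ndarray          # (n, 2) array of (row, col) pixel indices
    centroid: tuple[float, float]
    area_um2: float
    mean_intensity: float       # background-subtracted counts
    mean_potential: Optional[float] = None  # V


@dataclass(frozen=True)
class DomainHistogram:
    """Occurrence histogram of per-domain potentials with a Gaussian fit."""

    bin_centers: np.ndarray
    counts: np.ndarray
    gaussian_mu: float
    gaussian_sigma: float
    n_domains: int
    reliable: bool


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential fit A exp(-(t - t_start)/tau) + baseline.

    ``tau`` is in minutes and refers to the potential decay constant
    (intensity-scale fits use exp(-2(t - t_start)/tau) internally). ``flagged``
    marks non-decaying or degenerate series whose tau hit a bound.
    """

    amplitude: float
    tau: float
    baseline: float
    t_start: float
    rmse: float
    flagged: bool = False


def _robust_background(frame: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based robust sigma of the frame background."""
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def segment_domains(
    frame: np.ndarray,
    pixel_size: float,
    min_area: float | None = None,
    k_sigma: float = 3.0,
    cal: Optional[SHCalibration] = None,
    frame_index: int = 0,
) -> list[DomainRecord]:
    """Segment bright SH domains in one frame.

    Pixels above ``median + k_sigma * robust_sigma`` are grouped into
    4-connected components; components smaller than ``min_area`` (um^2;
    default 4 pixels) are dropped. Intensities are background-subtracted;
    when a calibration is given, each domain also carries the potential implied
    by the *median* signal over its pixels (robust against edge pixels and
    partial overlap with a neighbouring domain). A noise-free frame has zero
    robust spread; pixels strictly above the median are then taken directly,
    so a constant frame still yields no domains.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    px_area = pixel_size**2
    if min_area is None:
        min_area = 4 * px_area
    med, sigma = _robust_background(frame)
    mask = frame > med + k_sigma * sigma
    labels = measure.label(mask, connectivity=1)
    records: list[DomainRecord] = []
    for region in measure.regionprops(labels, intensity_image=frame):
        area = region.area * px_area
        if area < min_area:
            continue
        signal = max(region.intensity_mean - med, 0.0)
        med_signal = max(float(np.median(region.image_intensity[region.image])) - med, 0.0)
        pot = potential_from_intensity(med_signal, cal) if cal is not None else None
        records.append(
            DomainRecord(
                frame=frame_index,
                coords=region.coords.copy(),
                centroid=tuple(region.centroid),
                area_um2=area,
                mean_intensity=signal,
                mean_potential=pot,
            )
        )
    return records


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def domain_occurrence_histogram(
    domains: Sequence[DomainRecord],
    bins: int | np.ndarray = 24,
) -> DomainHistogram:
    """Histogram of per-domain mean potentials with a Gaussian least-squares fit.

    Domains from any number of frames are pooled (20 one-second frames is the
    convention emulated here). Fewer than 5 domains, or a degenerate spread,
    flags the fit as unreliable and falls back to sample moments.
    """
    pots = np.array([d.mean_potential for d in domains if d.mean_potential is not None])
    if pots.size == 0:
        raise ValueError("no domains with potentials to histogram")
    counts, edges = np.histogram(pots, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0, s0 = float(np.mean(pots)), float(np.std(pots))
    reliable = pots.size >= 5 and s0 > 0
    mu, sig = mu0, s0
    if reliable:
        try:
            p0 = [counts.max(), mu0, s0]
            popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
            mu, sig = float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            reliable = False
    return DomainHistogram(centers, counts, mu, sig, int(pots.size), reliable)


def mean_domain_potential_series(
    stack: np.ndarray,
    pixel_size: float,
    cal: SHCalibration,
    window: int = 20,
    min_area: float | None = None,
    k_sigma: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted mean domain potential per window of frames.

    Returns ``(window_start_indices, series)``; windows with zero detected
    domains are recorded as NaN (missing), never as zero.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be 3-D with at least 2 frames")
    n_windows = stack.shape[0] // window
    if n_windows < 2:
        raise ValueError("need at least 2 windows of frames")
    starts = np.arange(n_windows) * window
    series = np.full(n_windows, np.nan)
    for w, s in enumerate(starts):
        areas, pots = [], []
        for j in range(s, s + window):
            for d in segment_domains(stack[j], pixel_size, min_area, k_sigma, cal, j):
                areas.append(d.area_um2)
                pots.append(d.mean_potential)
        if areas:
            series[w] = np.average(pots, weights=areas)
    return starts, series


def _detect_t_start(times: np.ndarray, values: np.ndarray) -> float:
    """Post-peak start of the decaying part: argmax of a lightly smoothed series."""
    if values.size >= 5:
        kernel = np.ones(3) / 3.0
        smooth = np.convolve(values, kernel, mode="same")
    else:
        smooth = values
    return float(times[int(np.argmax(smooth))])


def fit_exponential_decay(
    times: Sequence[float],
    values: Sequence[float],
    t_start: float | None = None,
    scale: str = "potential",
    baseline: float | None = None,
) -> DecayFit:
    """Fit the decaying part of a series with a single exponential.

    ``times`` in minutes. ``scale='potential'`` fits A exp(-(t-t0)/tau) + b;
    ``scale='intensity'`` fits A exp(-2(t-t0)/tau) + b, because SH intensity is
    quadratic in the transmembrane potential — either way ``tau`` is the
    potential decay constant in minutes. ``t_start`` defaults to the post-peak
    maximum of the smoothed series. Passing a known ``baseline`` (e.g. the
    pre-acidification background level) pins b, which conditions the fit much
    better when the series spans only a couple of decay times. A non-decaying
    or flat series returns a flagged fit with tau pinned at a bound.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 4:
        raise ValueError("need at least 4 finite points to fit a decay")
    if scale not in ("potential", "intensity"):
        raise ValueError("scale must be 'potential' or 'intensity'")
    if t_start is None:
        t_start = _detect_t_start(t, y)
    sel = t >= t_start
    td, yd = t[sel] - t_start, y[sel]
    if td.size < 4:
        raise ValueError("fewer than 4 points after t_start")
    rate = 2.0 if scale == "intensity" else 1.0
    span = float(td.max() - td.min()) or 1.0
    amp0 = max(float(yd[0] - yd.min()), 1e-12)
    tau_hi = 1e4 * span
    tau0 = min(max(span / 2, 1e-3), tau_hi / 2)
    try:
        if baseline is None:
            def model(tt, amp, tau, base):
                return amp * np.exp(-rate * tt / tau) + base

            popt, _ = curve_fit(
                model, td, yd, p0=[amp0, tau0, float(yd.min())],
                bounds=([0.0, 1e-6, -np.inf], [np.inf, tau_hi, np.inf]),
                maxfev=10000,
            )
            amp, tau, base = map(float, popt)
        else:
            def model(tt, amp, tau):
                return amp * np.exp(-rate * tt / tau) + baseline

            popt, _ = curve_fit(
                model, td, yd, p0=[amp0, tau0],
                bounds=([0.0, 1e-6], [np.inf, tau_hi]),
                maxfev=10000,
            )
            amp, tau = map(float, popt)
            base = float(baseline)
    except RuntimeError:
        return DecayFit(0.0, math.inf, float(np.mean(yd)), t_start,
                        float(np.std(yd)), flagged=True)
    rmse = float(np.sqrt(np.mean((model(td, *popt) - yd) ** 2)))
    scatter = float(np.std(yd))
    flagged = tau >= 0.99 * tau_hi or amp <= 1e-6 * max(abs(base), 1.0) or amp < 1e-3 * scatter
    return DecayFit(amp, tau, base, float(t_start), rmse, flagged)


@dataclass(frozen=True)
class TauMap:
    """Per-ROI decay constants (min) and the fluxes (ions/s) they imply.

    ``tau`` and ``flux`` share one shape (the ROI grid); ROIs without a usable
    decaying signal hold NaN and are excluded from summary statistics.
    """

    tau: np.ndarray
    flux: np.ndarray
    roi_size: float  # um
    fits: list = field(default_factory=list, repr=False)

    def gaussian_summary(self, bins: int = 12) -> tuple[float, float]:
        """(mu, sigma) of a Gaussian least-squares fit to the tau histogram."""
        vals = self.tau[np.isfinite(self.tau)]
        if vals.size < 5:
            raise ValueError("too few fitted ROIs for a histogram summary")
        counts, edges = np.histogram(vals, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            popt, _ = curve_fit(
                _gaussian, centers, counts,
                p0=[counts.max(), float(np.mean(vals)), float(np.std(vals))],
                maxfev=5000,
            )
            return float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            return float(np.mean(vals)), float(np.std(vals))


def roi_tau_map(
    stack: np.ndarray,
    times: Sequence[float],
    pixel_size: float,
    roi_size: float = 4.5,
    t_start: float | None = None,
    window: int = 20,
    baseline_end: float | None = None,
    margin_px: int = 2,
    calibration_K: float = DEFAULT_TAU_FLUX_K,
) -> TauMap:
    """Map decay constants over a grid of square ROIs.

    The field is tiled into non-overlapping ``roi_size`` x ``roi_size`` um
    squares (edge remainders are discarded). Frames are averaged in blocks of
    ``window`` (domain appearances are uncorrelated between frames, so block
    averaging suppresses occupancy shot noise without distorting the slow
    envelope), and the mean intensity of each ROI per block is fitted with
    :func:`fit_exponential_decay` on the intensity scale. ``times`` are frame
    times in minutes. When ``t_start`` is not given it is detected once on the
    whole-field series (per-ROI peak detection would chase noise).
    ``baseline_end``, when given (the acidification time), fixes each ROI's
    fit baseline to its mean intensity before that time. ``margin_px`` strips
    a border from each ROI before averaging: domains straddling a tile
    boundary bleed signal between adjacent ROIs, and the resulting mixing of
    decay constants shrinks the apparent spatial spread of tau. ROIs whose fit
    is flagged (no decaying signal) are NaN in both maps.
    Flux = calibration_K / tau.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    t = np.asarray(times, dtype=float)
    if t.shape[0] != stack.shape[0]:
        raise ValueError("times must match the number of frames")
    roi_px = max(int(round(roi_size / pixel_size)), 1)
    n_r, n_c = stack.shape[1] // roi_px, stack.shape[2] // roi_px
    if n_r < 1 or n_c < 1:
        # field smaller than one ROI: use the whole field as a single ROI
        n_r = n_c = 1
        roi_px = min(stack.shape[1], stack.shape[2])
    window = max(min(window, stack.shape[0] // 4), 1)
    n_blocks = stack.shape[0] // window
    trimmed = stack[: n_blocks * window, : n_r * roi_px, : n_c * roi_px]
    m = margin_px if roi_px - 2 * margin_px >= 2 else 0
    # (blocks, n_r, n_c) mean intensity per ROI interior per block of frames
    tiled = trimmed.reshape(n_blocks, window, n_r, roi_px, n_c, roi_px)
    roi_means = tiled[:, :, :, m: roi_px - m, :, m: roi_px - m].mean(axis=(1, 3, 5))
    t_blocks = t[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    if t_start is None:
        t_start = _detect_t_start(t_blocks, roi_means.mean(axis=(1, 2)))
    pre = t_blocks < baseline_end if baseline_end is not None else None
    tau = np.full((n_r, n_c), np.nan)
    fits: list[list[DecayFit | None]] = []
    for r in range(n_r):
        row_fits: list[DecayFit | None] = []
        for c in range(n_c):
            base = float(roi_means[pre, r, c].mean()) \
                if pre is not None and pre.any() else None
            try:
                f = fit_exponential_decay(t_blocks, roi_means[:, r, c], t_start,
                                          scale="intensity", baseline=base)
            except ValueError:
                row_fits.append(None)
                continue
            row_fits.append(f)
            if not f.flagged:
                tau[r, c] = f.tau
        fits.append(row_fits)
    flux = np.where(np.isfinite(tau), calibration_K / tau, np.nan)
    return TauMap(tau=tau, flux=flux, roi_size=roi_px * pixel_size, fits=fits)


def tau_to_flux(tau: float, calibration_K: float = DEFAULT_TAU_FLUX_K) -> float:
    """Ion flux (ions/s) implied by a decay constant ``tau`` (min).

    Inverse proportionality anchored so a 67 min whole-membrane decay maps to
    7.5e6 ions/s; flux * tau = calibration_K for every tau.
    """
    if tau <= 0 or calibration_K <= 0:
        raise ValueError("tau and calibration_K must be > 0")
    return calibration_K / tau
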