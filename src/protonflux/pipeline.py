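"""End-to-end orchestration: conductivity, imaging and needle analyses.

Each ``run_*`` function consumes a validated :class:`~protonflux.config.RunConfig`,
executes one branch of the analysis, logs its stage counts at INFO, and
returns a JSON-serializable report section. :func:`run_all` combines them and
attaches a provenance block (config hash, package version, seed). Reports
carry no timestamps, so identical config + seed give byte-identical output.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import RunConfig
from .electro import (
    fit_iv,
    membrane_disk_area,
    permeability_from_current,
    permeability_from_flux,
    permeability_ratio_from_reversal,
    transported_moles,
)
from .imaging import (
    domain_occurrence_histogram,
    mean_domain_potential_series,
    roi_tau_map,
    segment_domains,
    tau_to_flux,
)
from .io import (
    iv_fit_report,
    read_iv_csv,
    read_profiles_csv,
    read_stack,
    write_domain_catalog,
    write_json,
)
from .needle import NeedleGeometry, needle_stabilization_energy, permeability_profile
from .shpotential import (
    bound_protons,
    charge_density_from_potential,
    interface_retention_fraction,
    round_sig,
)

log = logging.getLogger("protonflux")

__all__ = ["run_conductivity_analysis", "run_imaging_analysis",
           "run_needle_analysis", "run_all", "provenance"]


def provenance(config: RunConfig) -> dict:
    return {"config_sha256": config.digest(), "version": _version, "seed": config.seed}


def run_conductivity_analysis(config: RunConfig) -> dict:
    """Fit every I-V sweep, pick the steepest, and derive ratio/permeability/moles.

    The maximum-slope sweep (largest fitted conductance) provides the reversal
    potential; the H+/Cl- permeability ratio follows from Goldman inversion,
    the proton permeability from the GHK current at the configured bias, and
    the transported moles from the zero-bias current over the configured
    duration. Symmetric baths make the ratio undefined; the run continues with
    the ratio flagged.
    """
    if not config.iv_paths:
        raise ValueError("conductivity analysis needs at least one I-V file")
    cond = config.conditions.to_conditions()
    area_um2 = membrane_disk_area(config.membrane_radius_um)
    area_cm2 = area_um2 * 1e-8
    fits = [fit_iv(read_iv_csv(p), area=area_cm2) for p in config.iv_paths]
    log.info("conductivity: fitted %d I-V sweep(s)", len(fits))
    best = max(fits, key=lambda f: f.conductance)
    section: dict = {
        "fits": [iv_fit_report(f) for f in fits],
        "max_slope_label": best.label,
        "membrane_area_um2": area_um2,
        "conductance_S": best.conductance,
        "specific_conductance_S_per_cm2": best.specific_conductance,
        "reversal_potential_V": None if best.undefined_reversal else best.reversal_potential,
    }
    if best.undefined_reversal:
        section["permeability_ratio"] = None
        section["ratio_flag"] = "undefined (flat sweep)"
    else:
        try:
            section["permeability_ratio"] = permeability_ratio_from_reversal(
                best.reversal_potential, cond)
        except ValueError as err:
            section["permeability_ratio"] = None
            section["ratio_flag"] = str(err)
            log.warning("conductivity: permeability ratio undefined (%s)", err)
    u = config.ghk_bias_V
    vm = 0.0 if best.undefined_reversal else best.reversal_potential
    i_bias = best.conductance * (u - vm)
    try:
        section["ghk_current_A"] = i_bias
        section["permeability_ghk_cm_per_s"] = permeability_from_current(
            i_bias, u, cond, area_cm2).value
    except ValueError as err:
        section["permeability_ghk_cm_per_s"] = None
        section["ghk_flag"] = str(err)
    i_zero = best.conductance * (0.0 - vm)
    moles = transported_moles(i_zero, config.zero_bias_duration_s)
    section["zero_bias_current_A"] = i_zero
    section["transported_moles"] = moles
    return section


def run_imaging_analysis(config: RunConfig, conductivity_moles: float | None = None) -> dict:
    """Segmentation -> potential histogram -> decay fits -> tau/flux maps -> P.

    ``conductivity_moles`` (or ``config.conductivity_moles``) enables the
    interface-retention fraction against the capacitor-model charge
    accounting. A missing HCl-addition timestamp skips the decay fits with a
    warning (segmentation and histograms still run). The returned section
    carries the segmented window's domain records under the private key
    ``"_domains"`` (used for CSV catalogs; stripped before JSON output).
    """
    if config.stack_path is None:
        raise ValueError("imaging analysis needs a stack path")
    stack = read_stack(config.stack_path)
    if stack.shape[0] < 2 or not np.any(stack):
        raise ValueError(f"{config.stack_path}: empty or single-frame stack")
    meta = config.metadata
    cal = config.calibration.to_calibration()
    cond = config.conditions.to_conditions()
    px = meta.pixel_size_um
    times = np.arange(stack.shape[0]) * meta.frame_period_s / 60.0
    seg = config.segmentation
    log.info("imaging: %d frames of %s px", stack.shape[0], stack.shape[1:])

    section: dict = {"n_frames": stack.shape[0]}
    # occurrence histogram over the brightest window of frames
    frame_sums = stack.sum(axis=(1, 2))
    w = seg.window_frames
    n_windows = stack.shape[0] // w
    best_w = int(np.argmax(frame_sums[: n_windows * w].reshape(n_windows, w).sum(axis=1)))
    domains = []
    for j in range(best_w * w, (best_w + 1) * w):
        domains += segment_domains(stack[j], px, seg.min_area_um2, seg.k_sigma, cal, j)
    log.info("imaging: %d domains in window %d", len(domains), best_w)
    section["_domains"] = domains  # for the CSV catalog; stripped before JSON
    if domains:
        hist = domain_occurrence_histogram(domains)
        section["domain_histogram"] = {
            "mu_V": hist.gaussian_mu, "sigma_V": hist.gaussian_sigma,
            "n_domains": hist.n_domains, "reliable": hist.reliable,
        }
    starts, series = mean_domain_potential_series(
        stack, px, cal, window=w, min_area=seg.min_area_um2, k_sigma=seg.k_sigma)
    section["mean_domain_potential_series"] = {
        "t_min": (starts * meta.frame_period_s / 60.0), "potential_V": series}

    if meta.hcl_addition_min is None:
        log.warning("imaging: no HCl-addition timestamp; decay fits skipped")
        section["decay_flag"] = "no HCl-addition timestamp"
        return section

    tmap = roi_tau_map(stack, times, px, roi_size=config.roi_size_um,
                       window=config.roi_window_frames,
                       baseline_end=meta.hcl_addition_min)
    n_ok = int(np.isfinite(tmap.tau).sum())
    log.info("imaging: fitted %d/%d ROIs", n_ok, tmap.tau.size)
    whole = roi_tau_map(stack, times, px, roi_size=px * stack.shape[1],
                        window=config.roi_window_frames,
                        baseline_end=meta.hcl_addition_min)
    tau_field = float(whole.tau[0, 0]) if np.isfinite(whole.tau[0, 0]) else None
    section["roi_tau_map_min"] = tmap.tau
    section["roi_flux_map_ions_per_s"] = tmap.flux
    if n_ok >= 5:
        mu_t, sg_t = tmap.gaussian_summary()
        section["tau_histogram"] = {"mu_min": mu_t, "sigma_min": sg_t, "n_rois": n_ok}
    section["whole_field_tau_min"] = tau_field
    if tau_field is not None:
        flux = tau_to_flux(tau_field)
        area_cm2 = membrane_disk_area(config.membrane_radius_um) * 1e-8
        delta_c = (cond.h_bottom - cond.h_top) * 1e-3  # mol/cm^3
        section["whole_field_flux_ions_per_s"] = flux
        section["permeability_sh_cm_per_s"] = permeability_from_flux(
            flux, area_cm2, delta_c).value
    moles_cross = conductivity_moles or config.conductivity_moles
    if moles_cross is not None and domains:
        cap = config.capacitor.to_model()
        # capacitor-model accounting summed over the segmented window
        moles_bound = 0.0
        for d in domains:
            sigma = charge_density_from_potential(d.mean_potential or 0.0, cap)
            if sigma > 0:
                moles_bound += bound_protons(sigma, d.area_um2 * 1e-12).moles
        if moles_bound > 0:
            x = interface_retention_fraction(moles_cross, moles_bound)
            section["retention"] = {
                "moles_bound": moles_bound,
                "moles_translocated": moles_cross,
                "one_out_of": round_sig(x, 2),
            }
    return section


def run_needle_analysis(config: RunConfig) -> dict:
    """Permeability profiles per membrane, their ratios, and needle energies."""
    if not config.profile_paths:
        raise ValueError("needle analysis needs at least one profile file")
    cond = config.conditions.to_conditions()
    profiles = {Path(p).stem: read_profiles_csv(p) for p in config.profile_paths}
    section: dict = {"profiles": {}}
    for name, prof in profiles.items():
        pp = permeability_profile(prof, temperature=cond.temperature)
        section["profiles"][name] = {
            "xi": pp.xi, "P_relative": pp.P, "integral": pp.integral,
            "dominant_window": list(pp.dominant_window),
        }
    names = list(profiles)
    ratios = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ia = section["profiles"][names[a]]["integral"]
            ib = section["profiles"][names[b]]["integral"]
            if ib > 0:
                ratios[f"{names[a]}/{names[b]}"] = ia / ib
    section["integral_ratios"] = ratios
    grid = []
    for r_ang in (1.0, 2.0, 3.0):
        for u_mv in (100.0, 200.0, 300.0):
            geom = NeedleGeometry(radius=r_ang * 1e-10)
            grid.append({
                "radius_A": r_ang, "U_mV": u_mv,
                "stabilization_kJ_per_mol": needle_stabilization_energy(geom, u_mv * 1e-3),
            })
    section["needle_energy_grid"] = grid
    log.info("needle: %d profiles, %d energy grid points", len(profiles), len(grid))
    return section


def _flatten_scalars(report: dict, prefix: str = "") -> list[tuple[str, float]]:
    rows = []
    for key, val in report.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            rows += _flatten_scalars(val, prefix=name + ".")
        elif isinstance(val, (int, float)) and not isinstance(val, bool):
            rows.append((name, val))
    return rows


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run every branch for which the config supplies inputs.

    With ``out_dir`` set, writes ``report.json``, a flat ``report.csv`` of all
    scalar results, and — for imaging runs — the domain catalog and the
    tau/flux grids as CSV.
    """
    report: dict = {"provenance": provenance(config)}
    if config.iv_paths:
        report["conductivity"] = run_conductivity_analysis(config)
    if config.stack_path is not None:
        moles = report.get("conductivity", {}).get("transported_moles")
        report["imaging"] = run_imaging_analysis(config, conductivity_moles=moles)
    if config.profile_paths:
        report["needle"] = run_needle_analysis(config)
    domains = report.get("imaging", {}).pop("_domains", None)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json(out_dir / "report.json", report)
        pd.DataFrame(_flatten_scalars(report), columns=["quantity", "value"]).to_csv(
            out_dir / "report.csv", index=False)
        if domains:
            write_domain_catalog(out_dir / "domains.csv", domains)
        imaging = report.get("imaging", {})
        for key, stem in (("roi_tau_map_min", "tau_grid"),
                          ("roi_flux_map_ions_per_s", "flux_grid")):
            if key in imaging:
                pd.DataFrame(np.asarray(imaging[key])).to_csv(
                    out_dir / f"{stem}.csv", index=False, header=False)
    return report
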