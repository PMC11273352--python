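"""Seeded generators emulating the SH microscope and the patch amplifier.

Every generator returns the synthetic data *and* the ground truth that
produced it, so pipeline recovery tests always compare against the generator,
never against hard-coded constants. All randomness flows through
``numpy.random.default_rng(seed)``: the same seed reproduces the same data
bit for bit.

The image generator emulates time-lapse SH recordings of a planar bilayer
acidified on one side:

* transient bright domains appear independently in each frame (domain
  lifetimes are below the 1 s acquisition time, so frames are uncorrelated),
  with log-normal radii and Gaussian-distributed base potentials;
* after HCl addition the transmembrane potential follows a global
  rise-then-exponential-decay envelope; the decay constant tau varies over
  the field on a grid of tiles (truncated-Gaussian tau field), emulating
  spatially inhomogeneous proton translocation;
* pixel intensities follow the quadratic SH forward model applied to the
  envelope-modulated potentials (the envelope acts on the *potential*, so
  intensity decays twice as fast), plus shot (Poisson) and Gaussian read
  noise on top of a constant background.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .shpotential import SHCalibration, intensity_from_potential
from .electro import IVRecord
from .needle import DefectProfiles

__all__ = [
    "SHStackSpec",
    "GroundTruth",
    "gen_sh_stack",
    "gen_iv",
    "gen_defect_profiles",
    "envelope",
]


@dataclass(frozen=True)
class SHStackSpec:
    """Parameters of one synthetic SH acquisition.

    Defaults emulate the experiment this package analyses: a ~45 um field
    imaged at 1 s/frame over ~3.5 h (stored here at a 10 s frame period — an
    evenly subsampled long recording), HCl added at 10 min, potential peaking
    at 20 min, domain potentials ~ N(0.12, 0.05) V, and a tau field
    ~ N(42, 24) min truncated above 5 min on 4.5 um tiles.
    """

    field_size: float = 45.0          # um
    pixel_size: float = 0.45          # um
    frame_period: float = 10.0        # s
    n_frames: int = 1260
    birth_rate: float = 100.0         # domains per frame
    radius_median: float = 1.0        # um (log-normal)
    radius_sigma_log: float = 0.3
    potential_mu: float = 0.12        # V
    potential_sigma: float = 0.05     # V
    potential_floor: float = 0.005    # V truncation
    t_add: float = 10.0               # min, HCl addition
    rise_time: float = 10.0           # min, ramp to peak
    tau_mu: float = 42.0              # min
    tau_sigma: float = 24.0           # min
    tau_floor: float = 5.0            # min truncation
    tau_tile: float = 4.5             # um
    domain_lifetime: int = 1          # frames
    background: float = 20.0          # counts
    read_sigma: float = 2.0           # counts
    poisson: bool = True
    calibration: SHCalibration = field(default_factory=SHCalibration)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_size", "pixel_size", "frame_period", "radius_median",
                     "potential_sigma", "tau_tile", "tau_floor", "rise_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1 or self.domain_lifetime < 1:
            raise ValueError("n_frames and domain_lifetime must be >= 1")

    @property
    def n_pixels(self) -> int:
        return int(round(self.field_size / self.pixel_size))

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period / 60.0


def envelope(t_min, t_add: float, rise_time: float, tau: float):
    """Rise-then-decay potential envelope: 0 before ``t_add``, linear ramp to 1
    over ``rise_time``, then exp(-(t - t_peak)/tau)."""
    t = np.asarray(t_min, dtype=float)
    t_peak = t_add + rise_time
    env = np.where(
        t < t_add,
        0.0,
        np.where(t < t_peak, (t - t_add) / rise_time, np.exp(-(t - t_peak) / np.maximum(tau, 1e-9))),
    )
    return float(env) if np.isscalar(t_min) else env


@dataclass
class GroundTruth:
    """Everything the generator decided, for recovery tests and provenance.

    ``domains`` is a record array with per-domain frame, center (row, col, px),
    radius (px), base potential (V) and the envelope-modulated effective
    potential at its frame. ``tau_tiles`` is the tau field (min) at tile
    resolution; ``tau_of_domain`` gives each domain's local tau.
    """

    spec: Optional[SHStackSpec] = None
    domains: Optional[np.ndarray] = None
    tau_tiles: Optional[np.ndarray] = None
    iv_params: Optional[dict] = None
    profile_params: Optional[dict] = None

    def effective_potentials(self, frames: slice | np.ndarray | None = None) -> np.ndarray:
        if self.domains is None:
            raise ValueError("no domain ground truth recorded")
        pots = self.domains["effective_potential"]
        if frames is None:
            return pots
        sel = np.isin(self.domains["frame"], np.arange(self.spec.n_frames)[frames])
        return pots[sel]

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, SHCalibration):
                return asdict(o)
            raise TypeError(type(o))

        payload = {
            "spec": asdict(self.spec) if self.spec else None,
            "tau_tiles": self.tau_tiles,
            "iv_params": self.iv_params,
            "profile_params": self.profile_params,
        }
        if self.domains is not None:
            payload["domains"] = {name: self.domains[name] for name in self.domains.dtype.names}
        with open(path, "w") as fh:
            json.dump(payload, fh, default=default)


_DOMAIN_DTYPE = np.dtype([
    ("frame", np.int32),
    ("row", np.float64),
    ("col", np.float64),
    ("radius_px", np.float64),
    ("base_potential", np.float64),
    ("effective_potential", np.float64),
    ("tau", np.float64),
])


def gen_sh_stack(spec: SHStackSpec = SHStackSpec()) -> tuple[np.ndarray, GroundTruth]:
    """Generate a synthetic SH stack (frames, rows, cols) and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_px = spec.n_pixels
    tile_px = max(int(round(spec.tau_tile / spec.pixel_size)), 1)
    n_tiles = max(n_px // tile_px, 1)

    # truncated-Gaussian tau field at tile resolution (resample below the floor)
    tau_tiles = np.empty((n_tiles, n_tiles))
    flat = tau_tiles.reshape(-1)
    for k in range(flat.size):
        t = -math.inf
        while t <= spec.tau_floor:
            t = rng.normal(spec.tau_mu, spec.tau_sigma)
        flat[k] = t

    times = spec.frame_times_min
    stack = np.zeros((spec.n_frames, n_px, n_px))
    records = []
    yy = np.arange(n_px)

    for f in range(spec.n_frames):
        n_dom = rng.poisson(spec.birth_rate)
        rows = rng.uniform(0, n_px, n_dom)
        cols = rng.uniform(0, n_px, n_dom)
        radii_um = spec.radius_median * np.exp(rng.normal(0, spec.radius_sigma_log, n_dom))
        radii_px = np.maximum(radii_um / spec.pixel_size, 1.0)
        pots = rng.normal(spec.potential_mu, spec.potential_sigma, n_dom)
        pots = np.maximum(pots, spec.potential_floor)
        for life in range(spec.domain_lifetime):
            fi = f + life
            if fi >= spec.n_frames:
                break
            t = times[fi]
            for d in range(n_dom):
                r_t = min(int(rows[d] // tile_px), n_tiles - 1)
                c_t = min(int(cols[d] // tile_px), n_tiles - 1)
                tau = tau_tiles[r_t, c_t]
                env = envelope(t, spec.t_add, spec.rise_time, tau)
                phi = pots[d] * env
                if phi > 0:
                    signal = intensity_from_potential(phi, spec.calibration)
                    _render_disk(stack[fi], rows[d], cols[d], radii_px[d], signal)
                records.append((fi, rows[d], cols[d], radii_px[d], pots[d], phi, tau))

    clean = stack + spec.background
    if spec.poisson:
        noisy = rng.poisson(clean).astype(float)
    else:
        noisy = clean.copy()
    if spec.read_sigma > 0:
        noisy += rng.normal(0, spec.read_sigma, noisy.shape)

    gt = GroundTruth(
        spec=spec,
        domains=np.array(records, dtype=_DOMAIN_DTYPE),
        tau_tiles=tau_tiles,
    )
    return noisy, gt


def _render_disk(frame: np.ndarray, row: float, col: float, radius: float,
                 value: float) -> None:
    """Add a flat-top disk of the given value to the frame (additive overlap)."""
    r0 = max(int(math.floor(row - radius)), 0)
    r1 = min(int(math.ceil(row + radius)) + 1, frame.shape[0])
    c0 = max(int(math.floor(col - radius)), 0)
    c1 = min(int(math.ceil(col + radius)) + 1, frame.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    frame[r0:r1, c0:c1][mask] += value


def gen_iv(
    G: float,
    V_rev: float,
    n_points: int = 11,
    noise_sigma: float = 0.0,
    seed: int = 0,
    v_min: float = -0.06,
    v_max: float = 0.06,
    label: str = "synthetic",
) -> tuple[IVRecord, GroundTruth]:
    """Synthetic near-linear I-V sweep: I = G (V - V_rev) + N(0, noise_sigma)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    v = np.linspace(v_min, v_max, n_points)
    i = G * (v - V_rev)
    if noise_sigma > 0:
        i = i + rng.normal(0, noise_sigma, n_points)
    gt = GroundTruth(iv_params={"G": G, "V_rev": V_rev, "noise_sigma": noise_sigma,
                                "seed": seed, "n_points": n_points})
    return IVRecord(voltages=v, currents=i, label=label), gt


def gen_defect_profiles(
    barrier_height: float = 40.0,
    barrier_xi: float = 0.83,
    flux_scale: float = 1.0e7,
    flux_onset: float = 0.75,
    flux_width: float = 0.012,
    linear_frac: float = 0.3,
    steepness: float = 14.0,
    n_points: int = 46,
    noise_sigma: float = 0.0,
    voltage: float = 0.3,
    seed: int = 0,
) -> tuple[DefectProfiles, GroundTruth]:
    """Smooth synthetic defect free-energy and flux profiles over xi in [0.1, 1].

    dG rises gently (linear share ``linear_frac`` of ``barrier_height``) and
    then steeply past ``barrier_xi`` (softplus wall of sharpness ``steepness``)
    toward the open-pore end; the flux switches on sigmoidally near
    ``flux_onset`` (water-wire connectivity). ``barrier_height`` (kJ/mol) is
    the free energy at xi = 1. Optional Gaussian noise (kJ/mol on dG, relative
    on flux) is seeded.
    """
    if barrier_height <= 0:
        raise ValueError("barrier_height must be > 0")
    rng = np.random.default_rng(seed)
    xi = np.linspace(0.1, 1.0, n_points)
    s = (xi - 0.1) / 0.9
    k = steepness / max(1.0 - barrier_xi, 1e-6)
    sp = lambda x: np.log1p(np.exp(np.clip(x, -50.0, 50.0)))
    wall = sp(k * (xi - barrier_xi)) - sp(k * (0.1 - barrier_xi))
    wall = wall / (sp(k * (1.0 - barrier_xi)) - sp(k * (0.1 - barrier_xi)))
    dG = barrier_height * (linear_frac * s + (1 - linear_frac) * wall)
    flux = flux_scale / (1.0 + np.exp(-(xi - flux_onset) / flux_width))
    if noise_sigma > 0:
        dG = dG + rng.normal(0, noise_sigma, n_points)
        dG -= dG[0]  # keep the offset convention
        flux = np.abs(flux * (1 + rng.normal(0, noise_sigma / barrier_height, n_points)))
    gt = GroundTruth(profile_params={
        "barrier_height": barrier_height, "barrier_xi": barrier_xi,
        "flux_scale": flux_scale, "flux_onset": flux_onset,
        "flux_width": flux_width, "linear_frac": linear_frac,
        "steepness": steepness, "noise_sigma": noise_sigma, "seed": seed,
    })
    return DefectProfiles(xi=xi, dG=dG, flux=flux, voltage=voltage), gt
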