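# Methods

`protonflux` quantifies proton translocation across free-standing planar lipid
bilayers from two experimental channels — second-harmonic (SH) imaging of
interfacial water and current–voltage (I–V) recordings — and connects them to
a molecular picture of transient water needles. This note records the models,
the estimators, the defaults, and the choices made where the design was open.

## Electrodiffusion model

The membrane separates a *bottom* compartment (acidified to pH 4.1 by HCl
addition, total ionic strength 61 mM) from a *top* compartment (pH 7.3,
50 mM KCl). Two ions are treated as conducted: H⁺ and Cl⁻. Activities are
identified with concentrations ([H⁺] = 10^(−pH)); buffer species enter only
through the ionic strength. The default temperature is 296.15 K (room
temperature), configurable everywhere.

**Reversal potential.** For permeability ratio r = P_H/P_Cl,

    V_m = (RT/F) · ln[ (r·[H]_bottom + [Cl]_top) / (r·[H]_top + [Cl]_bottom) ],

oriented so acid on the bottom with r > 1 gives V_m > 0. The inversion for r
is algebraic (`permeability_ratio_from_reversal`), valid only for V_m strictly
between the Cl⁻ and H⁺ Nernst potentials (−5.1 mV and +188 mV at the default
conditions); the symmetric-bath case is ill-posed and raises.

**GHK flux equation.** The proton current at bias U is

    i = P z²F²·U·A/(RT) · (c_in − c_out·e^(−zFU/RT)) / (1 − e^(−zFU/RT)),

with concentrations in mol/cm³, P in cm/s, A in cm². The *top* (resting-pH)
compartment is taken as "inside": this assignment reproduces the measured
permeability scale from the (−7.6 pA, −60 mV) working point, whereas the
opposite choice is off by an order of magnitude. |U| below ~25 nV switches to
the series expansion (Fick's law at U = 0). The inversion for P is exact
(linearity in P) and round-trips to 1e−9.

**Flux route.** Imaging-derived fluxes convert to permeability as
P = F/(N_A·A·Δc) with Δc the transmembrane proton concentration difference.
The unstirred-layer bound P_UL = D/δ (defaults D = 5e−6 cm²/s, δ = 200 µm
give 2.5e−4 cm/s) confirms the membrane, not the aqueous layers, limits
transport at the measured 1e−6 cm/s scale.

**I–V fitting** is ordinary least squares; G = slope, V_m = −intercept/slope.
"Maximum slope" selection across sweeps = largest fitted G. A slope of zero
flags the reversal potential as undefined rather than emitting ±inf.

**Gouy–Chapman–Stern.** The diffuse-layer potential inverts the Grahame
equation in closed form (asinh); an optional Stern capacitance adds σ/C_stern.
At 60 mM ionic strength a 350 mV surface potential would require > 5 C/m²
of bare lipid charge without a condensed layer — far beyond a lipid monolayer
(≈ 0.2–0.4 C/m² fully charged) — but becomes attainable with C_stern ≈ 1 F/m²,
which is why the high domain potentials imply a Stern layer.

## SH intensity → potential

A symmetric bilayer emits no coherent SH; a transmembrane potential ΔΦ₀
polarizes interfacial water, giving

    I = intensity_scale · (χ⁽²⁾_eff + χ⁽³⁾′·ΔΦ₀)².

The default χ⁽²⁾_eff = 0 (symmetric membrane) makes ΔΦ₀ ∝ √I. Intensity does
not carry the sign of ΔΦ₀, so magnitudes are reported. Calibration is either
a user-supplied (intensity_scale, χ⁽³⁾′) pair or an anchor: one measured
intensity pinned to a known potential (e.g. from capacitance minimization).

**Charge accounting.** Each domain is an independent parallel-plate capacitor
(C = ε₀ε/d; ε = 2.1, d = 4 nm ⇒ 0.465 µF/cm²): Δσ = C·ΔΦ, bound protons
N = Δσ·A/e. Counts are kept unrounded until reporting; the retention fraction
(moles crossed per mole bound) is printed at two significant figures.

## Image pipeline

* **Segmentation**: threshold at background median + k·(1.4826·MAD), default
  k = 3; 4-connected components; minimum area 4 pixels. Both constants are
  configurable; recovery tests always compare against generator ground truth,
  not against these constants. A domain's potential is computed from the
  *median* background-subtracted intensity over its pixels — the median is
  insensitive to edge pixels and to partial overlap with a neighbouring
  domain, which bias the mean upward at realistic domain densities.
* **Occurrence histograms** pool per-domain potentials over a 20-frame window
  and fit a Gaussian to the binned counts (figure-style (µ, σ)); fewer than 5
  domains or zero spread flags the fit unreliable.
* **Decay fitting.** SH intensity is quadratic in the potential, so when a
  *potential* decays as exp(−t/τ) the *intensity* decays as exp(−2t/τ).
  `fit_exponential_decay(scale="intensity")` fits the squared model and always
  reports τ on the potential scale; the whole-field ⟨ΔΦ_domain⟩ series is
  fitted on the potential scale directly. τ is therefore one consistent
  quantity across both routes. The fit start defaults to the post-peak
  maximum of the lightly smoothed series ("the decaying part"); when the
  acidification time is known, the pre-addition intensity fixes the fit
  baseline, which conditions slow decays (τ comparable to the recording
  length) far better than a free baseline.
* **ROI τ maps** tile the field into non-overlapping squares (default
  4.5 µm). Frames are averaged in blocks (default 20) before fitting — domain
  appearances are uncorrelated frame-to-frame, so block averaging suppresses
  occupancy shot noise without distorting the slow envelope. A 2-pixel
  interior margin is stripped from each ROI before averaging: domains
  straddling a tile boundary bleed intensity into the neighbouring ROI, and
  without the margin this cross-talk mixes decay constants and shrinks the
  apparent spatial spread of τ by ~15%. ROIs without a decaying signal are
  missing values (NaN), excluded from histograms.
* **τ → flux** by inverse proportionality with one anchor pair,
  K = τ_ref·F_ref = 67 min · 7.5e6 ions/s. This single-constant form
  reproduces both reference fluxes (7.5e6 ions/s at 67 min; 1.2e7 ions/s at
  42 min) and keeps flux·τ invariant.

## Water-needle model

Defect formation along the chain coordinate ξ_ch (0.1 = intact membrane,
≈ 0.74 = water needle, 1 = open pore) is characterized by a free-energy
profile ΔG(ξ) (kJ/mol, zero at the intact end) and a per-defect proton flux
F(ξ). The permeability profile is the Boltzmann-weighted product

    P(ξ) ∝ F(ξ) · exp(−ΔG(ξ)/RT),

reported in relative units (an absolute scale would need an MD-calibrated
prefactor, out of scope). The *dominant window* is the smallest ξ interval
containing ≥ 90% of ∫P dξ. Adding a constant to ΔG rescales P globally and
leaves the normalized shape and the window unchanged, so relative profiles
sidestep any normalization ambiguity.

The electrostatic stabilization of a needle by a transmembrane potential is
the dielectric-replacement energy of a water cylinder (ε_w = 80) replacing
membrane (ε_m = 2.1) in the uniform field U/d of the membrane capacitor:

    ΔW = ½ε₀(ε_w − ε_m)(U/d)²·πr²d,

quadratic in both U and r. At r = 3 Å, U = 300 mV, d = 4 nm this gives
1.32 kJ/mol (≈ ½ k_BT) — needle formation is essentially potential-
independent at physiological-scale fields. The tests confirm the formula
against a numerical field-energy integration of the pixelated cylinder
cross-section (agreement to < 5%, limited by circle pixelation).

## Synthetic data: what it emulates, what it does not

The stack generator emulates: transient bright domains with lifetimes below
one frame (uncorrelated frames; lag-1 occupancy autocorrelation ≈ 0),
log-normal domain radii (median 1 µm — a placeholder, the true size
distribution is not constrained), Gaussian base potentials
(µ = 0.12 V, σ = 0.05 V, floored at 5 mV), a rise-then-exponential-decay
envelope applied to the *potential* (HCl addition at 10 min, 10 min ramp),
a truncated-Gaussian τ field (µ = 42, σ = 24, > 5 min) constant on 4.5 µm
tiles, and Poisson shot noise plus Gaussian read noise over a constant
background. The default acquisition is a 45 µm field at 0.45 µm/pixel,
1260 frames at one frame per 10 s (3.5 h) — standing in for an hours-long
1 s/frame recording at the statistics the per-ROI decay fits need
(~10³ domain appearances per ROI).

Not emulated: optical point-spread and speckle, drift, photobleaching,
flat-field structure, spatially correlated domain nucleation, per-leaflet
χ⁽²⁾ asymmetries. Passing recovery tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to every
optical artifact of real recordings.

Every generator emits its `GroundTruth`; recovery tests compare against it,
never against hard-coded numbers. The recovery harness
(`protonflux.validation`) matches detected domains to ground-truth domains by
centroid (within 2 px + the domain radius) and compares like-for-like:
the same estimator applied to the matched truth values. Gaussian parameters
in the *comparison* are maximum-likelihood (sample moments); the binned
histogram fit is retained for figure-style output but is far noisier at
~100 samples. Overlapping domains merge under any threshold segmentation, so
per-domain recovery is stated as a population property (median error ≈ 0;
≥ 85% of matched domains within the error band) rather than a per-domain
guarantee.

## Numerical choices and degenerate inputs

* Root-finding uses closed forms wherever they exist (Goldman and Grahame
  inversions, GHK linearity); `brentq` appears only in the charge-for-
  potential inversion and in test oracles.
* GHK at |zFU/RT| < 1e−9 switches to the first-order expansion (exact limit).
* Decay fits bound τ ∈ (1e−6, 1e4·span] min and flag fits pinned at the
  bound, with amplitude ≈ 0, or with amplitude below 1e−3 of the series
  scatter (non-decaying input).
* Constant frames segment to zero domains; noise-free frames (zero MAD) fall
  back to a strict above-median threshold.
* Empty windows in the ⟨ΔΦ_domain⟩ series are NaN (missing), never zero.
* Reports carry no timestamps; identical config + seed reproduce reports
  byte-for-byte.

## Known limitations

* Potential magnitudes only; leaflet-resolved signs require a χ⁽²⁾ model the
  intensity alone cannot fix.
* The τ → flux conversion assumes strict inverse proportionality through one
  anchor pair; a mechanistic conversion would need the interface-retention
  chain reconstructed per membrane.
* Absolute P(ξ) values are out of scope (relative profiles only).
* The GCS solver treats a symmetric 1:1 electrolyte; mixed-valence baths are
  reduced to an effective ionic strength by the caller.
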