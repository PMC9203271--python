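# Methods

## 1. Single-macropinosome ion/volume model

### State and algebraic closures

The model (`mpresolve.vesicle_model`) integrates luminal amounts (mol) of
Na⁺, K⁺ and Cl⁻, the cumulative buffered proton load `n_Hbound`, and the
luminal pH. Two impermeant pools are fixed at initialization: a neutral
osmolyte pool `n_X` (glucose, HEPES, dextran) that pads the initial lumen
to the external osmolarity, and a charged pool `n_A` with a mean valence
(divalent cations of the imaging buffer; gluconate or NMDG⁺ in the
substitution scenarios) that closes initial electroneutrality.

Two quantities are algebraic, not dynamic:

* **Volume.** Water permeability is treated as infinite, so at every
  instant Σ osmolytes / V = Osmₑₓₜ, i.e. `V = Σnᵢ / Osm_ext`. Free protons
  are excluded from the osmotic sum (they are buffered, hence osmotically
  inactive) and K⁺ and the impermeant pools act as the non-extrudable
  osmolyte floor that ultimately limits shrinkage.
* **Membrane potential.** `U = F·Δq / (c_m·A)` with A the area of the
  equivalent sphere. The initial +70 mV (lumen positive) is realized as a
  charge offset on the capacitance; afterwards U follows the integrated
  net charge of all fluxes. Because the capacitive charge (~10⁻²⁰ mol) is
  tiny compared with the ion pools (~10⁻¹⁶ mol), the lumen is effectively
  electroneutral and U relaxes on the c_m/g timescale (seconds).

### Flux laws

All fluxes are in mol/s into the lumen; voltages in the lumen-minus-cytosol
convention (lumen-negative U is what an outwardly rectifying channel on an
endosome experiences as activating).

| pathway | law |
|---|---|
| TPC (Na⁺) | ohmic, always open: J = −g·A·(U−E_Na)/F |
| ASOR (Cl⁻) | ohmic × open fraction f_pH(pH)·f_U(U) |
| H⁺ conductance | ohmic × Boltzmann activation at lumen-negative U |
| CLC 2Cl⁻/H⁺ | rate = k·A·p_U·p_pH·(U_rev − U); one cycle = 2 Cl⁻ out, 1 H⁺ in, +3 charges in |
| V-ATPase | J = J_max·A·max(0, 1 − pmf/pmf_stall) |

ASOR's acid activation is a Hill-type sigmoid in pH (midpoint 5.3, three
decades of opening per pH unit) and its voltage activation a Boltzmann; the
two multiply (separable gating). The CLC reversal voltage comes from the
exact cycle free energy, so the exchanger's flux is identically zero at
thermodynamic equilibrium — the late-time regime in which CLCs idle near
equilibrium and buffer the pH falls out of this form without extra terms.
Proton influx moves pH through a constant buffer capacity β:
dpH/dt = −J_H/(β·V).

The NH₄Cl condition is phenomenological: a one-sided relaxation keeps the
lumen at or above pH 7.0 (weak-base partitioning is not modelled). The
`gating_removed` condition pins the ASOR and CLC open fractions at 1.

### Parameters

Defaults (mostly `TransporterParams`):

| parameter | value | units | rationale |
|---|---|---|---|
| g_TPC | 0.33 | S/m² | sets the overall resolution rate; TPC-limited late phase |
| g_ASOR | 200 | S/m² | deep in the feedback-saturated regime (resilience) |
| k_CLC | 1.5·10⁻⁶ | mol/(s·m²·V) | "minor contribution" to Cl⁻ exit; dominant Cl⁻→pH coupling in the knockout |
| g_H | 0.02 | S/m² | small acid leak/secondary acidifier |
| J_pump_max | 6·10⁻⁸ | mol/(s·m²) | fast pump: pH reaches its brake within minutes |
| pmf_stall | 120 | mV | the pump's stall is the pH brake; it couples pH to U (see below) |
| pH_half_ASOR / n | 5.3 / 3 | pH / decades | measured half-activation; "steep" |
| U_half_ASOR / k | −50 / 14 | mV | opens only lumen-negative; sets the late-volume plateau |
| U_half_CLC / k | −20 / 10 | mV | opens at cytoplasmic potentials beyond ~+20 mV |
| pH_half_CLC / floor | 6.0 / 0.3 | — | partial acid inhibition of CLC transport |
| β | 30 | mM/pH | HEPES-buffered medium plus dextran/protein; sets retained Cl⁻ (see below) |
| c_m | 0.01 | F/m² | 1 µF/cm² |
| cytosol | Na 15, K 145, Cl 40 mM, pH 7.2 | | tenfold Na⁺ gradient against the 150 mM lumen; textbook values |
| lumen (t=0) | Na 150, K 5, Cl 159 mM, pH 7.2, 320 mOsm | | imaging buffer engulfed at closure |
| r₀ | 1.0 | µm | typical MP |

Two of these deserve an explicit account, because the design space was
genuinely open:

* **Pump stall at 120 mV.** With a stall far above the operating range the
  pump is an open-loop acid source: luminal pH becomes a pure race between
  delivery and time, every intervention that touches timing moves the pH
  endpoint, and the ASOR copy-number resilience property fails (a ten-fold
  density change shifts the 10-min volume by ~30 %). Placing the stall at
  120 mV makes the pump *self-limiting*: pH slides quickly to the stall
  locus pH ≈ pH_cyt − (pmf_stall − U)/61.5 and then tracks it. This single
  choice yields, without further tuning, the voltage→pH couplings seen in
  the data: the wild type (U ≈ −10…−20 mV late) settles near pH 5.5; the
  knockout and the low-chloride lumen (U ≈ −40…−60 mV) settle more acidic;
  and a ten-fold ASOR change moves the 10-min volume by <10 %.
* **Buffer capacity 30 mM/pH.** Every buffered proton that enters the lumen
  electrically retains one Cl⁻. The total proton load therefore sets how
  much Cl⁻ (and volume) remains when Na⁺ is exhausted; β = 30 mM/pH puts
  the 10-min volume plateau at ~19–20 % of the initial volume.

The transporter densities were calibrated once against the two published
endpoints of the wild-type condition (≈20 % volume, pH ≈5.5 at 10 min) and
the qualitative intervention orderings, then frozen; nothing is re-fit at
run time.

### Scenario presets

`make_scenario(name)` reproduces each condition from the table alone:
`WT`; `TMEM206_KO` (g_ASOR = 0); `low_luminal_Cl` (Cl⁻ 159→9 mM, gluconate
as impermeant anion); `low_luminal_Na` (Na⁺→1 mM, NMDG⁺ impermeant);
`bafilomycin` (pump off); `NH4Cl` (pH clamp ≥7); `CLC_only` (TPC + CLC
only); `Hcond_only` (TPC + ASOR + H⁺ conductance); `R87C` (ASOR pH midpoint
shifted to 7.4); `gating_removed`; `copy_number_scan` (= WT, used with
`scan_copy_number`).

### Numerics

LSODA with rtol 10⁻⁸ and per-variable atol (10⁻¹⁰ of the total osmolyte
content for amounts); outputs on a 1 s grid. V and U are recomputed
algebraically inside the right-hand side; no water ODE exists. Degenerate
inputs are rejected up front: non-electroneutral or hyper-osmotic initial
lumina, negative densities, unknown scenario names. The two-species
(Na/Cl + impermeant) configuration relaxes to the Donnan equilibrium
computed by an independent root-finder to 10⁻⁶ relative, including the
capacitor charge.

## 2. Synthetic microscopy

The generator (`mpresolve.synthetic_imaging`) emulates the statistical
structure the quantification assumes: homogeneous spherical vesicles whose
intensity is proportional to luminal dye concentration (dye conserved, so
shrinkage brightens), sectioned into z-planes (0.6 µm step), blurred with
an isotropic Gaussian PSF (σ 1.5 px), composited over cell-shaped
cytoplasm regions and background, and corrupted by Poisson and Gaussian
read noise. Pixel size 0.11 µm, one frame/min, 11 frames. Vesicles move as
a bounded random walk (≤3–5 px/frame, well under the 30 px tracking gate).
The dual-excitation mode renders a pH-insensitive channel (∝ concentration)
and a pH-sensitive channel scaled by a unit-Hill sigmoid with midpoint at
the reporter pKa 4.7; the scratch generator fills a field with blob-like
cells (sd 5 px), clears a band at t = 0, and lets cells enter it at a
Poisson rate with a mutual exclusion radius.

`render_benchmark` defines the standard operating point for the detector:
20 vesicles of 12 px initial radius on a 300×300 frame, with vesicle
contrast over cytoplasm equal to `snr` times the cytoplasmic noise sd
(shot + read). `simulate_then_render` couples the ODE output to the
renderer (radius ∝ V^{1/3}, conserved dye, optional simulated pH in the
reporter channel).

Not emulated: photobleaching, stage drift, depth-dependent PSF, camera
fixed-pattern noise, vesicle fission/fusion, non-spherical MPs. Passing
the end-to-end tests therefore demonstrates internal consistency of the
measurement chain under the stated image model, not performance on real
microscope data.

## 3. MP detection

`mp_detection` runs, per frame: maximum z-projection → histogram truncation
to the [15th, 95th] percentile band → cell segmentation (inverse Gaussian
gradient, α = 100, σ = 5 px, thresholded below its own 30th percentile,
traces filled to a mask) → difference-of-Gaussians blob proposal (kernel sd
1–15 px, response floor 0.01) on the masked image → per-candidate
confirmation in a 50×50 px crop: Canny edges (σ = 4, hysteresis 0/100) and
a circular Hough transform over radii 3–35 px. Of the five strongest
accumulator peaks, at least two centres must lie within 5 px of the
candidate; the radius is the 95th percentile of those qualifying radii.

Conventions the recipe leaves open, fixed here:

* Percentiles use linear interpolation throughout.
* Images are min–max scaled before the DoG stage (the response floor is
  then a fraction of the frame's dynamic range) and to a 16-bit-like range
  before Canny (the 0/100 hysteresis pair assumes that scale).
* The cell-segmentation percentile is taken on the filtered (gradient)
  map, and the mask gates only the *blob proposal*; the Hough crop is cut
  from the unmasked truncated projection, because a zeroed surround
  introduces a mask-boundary edge that out-competes the vesicle ring in
  the edge detector's non-maximum suppression.
* Hough peaks are enumerated in descending accumulator order with one
  circle per centre pixel (ties: smaller radius, then row-major centre).
  Keeping near-concentric circles at adjacent centres is what makes the
  2-of-5 concentricity rule discriminative.
* Detections closer than 5 px are merged (most qualifying circles wins):
  several blob proposals can hit one vesicle.
* Coordinates are 0-based (row, col) floats; border crops are zero-padded.

At the standard benchmark (20 vesicles, SNR 5) the detector reaches
recall ≥ 0.9, precision ≥ 0.9 and a radius MAE ≤ 1 px, and recall degrades
monotonically as read noise grows at fixed dye.

A practical note on the histogram truncation: because the clip level is the
image's own 95th percentile, the apparent vesicle radius is only unbiased
while the bright (vesicle) pixel population stays above ~5 % of the frame.
The end-to-end fixtures keep the vesicle area fraction above that bound at
every frame (28 vesicles, r₀ 16 px on 300²); sparser movies acquire a
radius bias of order +1 px as the clip level slides down the PSF skirt.

## 4. Tracking, volume, intensity, pH

Tracks are seeded from the detections of the *last* frame (shrunken MPs are
brightest there) and extended backward; candidate links are taken in
ascending centre-distance order, each detection used at most once, and a
link is accepted only if the displacement is ≤ 30 px (3.3 µm; the bound is
inclusive). Merging of two tracks onto one earlier detection is not
allowed. Detections never claimed by the backward pass are discarded.
Gaps are recorded, never interpolated; downstream aggregation keeps tracks
spanning at least 6 of 11 frames (configurable).

Volume is (4/3)π(r·0.11 µm)³; intensity is the mean over an inner circle of
radius r/2 on the untruncated projection. Ratiometric pH: per frame and
channel, the background is the 2nd percentile of the whole projected image;
the ratio is corrected-515 over corrected-445, frames with non-positive
corrected 445 are flagged invalid. The calibration is a four-parameter
logistic in pH, fitted by least squares to (pH, ratio) points (≥4 distinct
pH values spanning ≥2 units, increasing overall); its closed-form inverse
maps ratios to pH, with out-of-range ratios reported as missing rather than
extrapolated.

End-to-end recovery is asserted on the *median* across tracks (a single
mis-linked track with a spurious first-frame radius would otherwise
dominate the mean of the cubed ratios). The noise-free reporter pipeline
recovers a pH 4.5–7.5 grid within 0.2 units; with realistic noise the
usable range narrows to the flank of the reporter sigmoid, as for the real
dye.

## 5. Scratch assay

On the t = 0 frame: inverse-Gaussian-gradient map (α = 100, σ = 5)
thresholded below its 20th percentile marks textured pixels; a local
adaptive threshold (block 41, offset 10) marks pixels well below their
local mean (inter-cell shadows); the wound candidate is the smooth
remainder, opened with a 40 px disk and stabilised by two morphological
reconstructions — by dilation from an eroded seed, then by erosion from a
dilated seed (the other order is available via configuration, as the
original operator order is ambiguous). The wound is the longest boundary
contour *by perimeter* (the mask is padded first so border-touching wounds
still close); its shoelace area converts to µm² at 0.55 µm/px exactly.
Cells are counted per frame as DoG blobs (sd 5–30 px, floor 0.02) whose
centres fall inside the t = 0 mask, and reported as
(count − count₀)/area — negative values are reported as-is.

## 6. Hierarchical statistics

Measurements nest as MP → dish → animal (preparation). Group values
average per dish, then per animal; the reported n is the number of
animals and the s.e.m. is taken over animal means. Volume time courses are
normalised per track to the first observed timepoint. Both operations are
permutation-invariant and scale-equivariant, and incomplete provenance
keys are an error rather than a silent drop.

## 7. Known limitations

* The flux laws are the simplest thermodynamically consistent forms that
  satisfy the stated gating phenomenology (ohmic channels rather than GHK;
  linear distance-from-reversal CLC kinetics; linear pump stall). Absolute
  currents are not calibrated to patch-clamp data.
* K⁺ has no pathway; divalents, gluconate and NMDG⁺ are lumped into a
  single impermeant pool; NH₄Cl is a pH clamp, not a weak-base flux model.
* The `Hcond_only` preset shrinks only mildly: with the pump off, a pure
  H⁺ conductance equilibrates near E_H and cannot acidify far below
  pH ≈ pH_cyt + U/61.5, so ASOR opens weakly. A stronger H⁺ conductance or
  residual pump activity changes this quantitatively.
* Detector radii are integer-quantized by the Hough accumulator; volume
  ratios inherit a ±(1 px)³ granularity. The end-to-end tolerance of 15 %
  on the 10-minute volume fraction reflects this.
* The synthetic image model is deliberately minimal (Section 2); benchmark
  numbers are statements about the pipeline, not about real microscopes.
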