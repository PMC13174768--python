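# Methods

This note documents the physical models, numerical conventions and
design choices behind `pptsim`, and what its synthetic studies do and do
not establish.

## Scope and model chain

`pptsim` simulates the imaging physics of pair production tomography for
a 2.617 MeV gamma line: isotropic emission from a voxelized source map,
photon transport to first (and, optionally, subsequent) interactions,
pair production with explicit positron follow-up, annihilation-photon
generation, idealized PET-ring detection, and list-mode reconstruction.
It deliberately excludes detector microphysics (depth of interaction,
inter-crystal scatter, dead time), real-scanner data formats, CT-based
corrections, and three-photon annihilation.

## Embedded physical data

* **Attenuation coefficients** (`pptsim.tables`): per-channel linear
  coefficients (photoelectric, Compton, pair production; cm⁻¹) on a
  16-point grid spanning 0.05–3 MeV for water, adipose, inflated lung
  (ρ = 0.26 g/cm³), brain, cortical bone and air (ICRU-44-style
  compositions).  The Compton channel is the Klein–Nishina total cross
  section times electron density — exact for free electrons and accurate
  to ~1% above 0.1 MeV; the pair channel is anchored to standard water
  values (so the embedded water total reproduces the familiar
  1/μ = 23.4 cm mean free path at 2.617 MeV to 0.3%) and scaled across
  materials with the Z(Z+1)/A composition factor, folding triplet
  production into the same channel; the photoelectric channel uses an
  effective-Z power law anchored at 50 keV and is negligible above
  1 MeV.  Interpolation is log–log and exact at grid nodes; the pair
  channel rises as (E − E_th)³ just above threshold.  Below ~0.1 MeV the
  photoelectric parametrization is approximate — adequate here because
  the 50 keV photon cutoff makes that region irrelevant to every
  reported observable.
* **Positron stopping data**: CSDA mass ranges (g/cm²) on a 0–2 MeV
  grid, ESTAR-style for water; cortical bone carries its own table
  (water scaled by the Z/A stopping ratio); other tissues share the
  water mass-range curve and differ by density.  Radiation lengths (for
  multiple scattering) come from the PDG per-element formula mixed by
  mass fraction.
* **Decay-chain spectrum**: the main γ lines of the ²¹²Pb chain with
  intensities per parent decay; the 2.617 MeV line carries 0.36.  The
  imaging studies emit monoenergetic 2.617 MeV primaries, matching how
  the physics is characterized; the spectrum exists for source modelling
  and energy-window reasoning (e.g. the 239 keV line falls outside the
  435–585 keV window).

## Photon transport

Free paths are sampled by Woodcock delta-tracking with the majorant
taken over the materials present in the grid, which is exact for voxel
media and costs one coefficient lookup per tentative collision.
Accepted collisions choose a channel proportional to the local
(μ_pe, μ_C, μ_pair).  Compton scattering samples ε = E′/E from
Klein–Nishina by rejection under the (ε + 1/ε) envelope; scattered
photons are re-tracked until escape or E < 50 keV (configurable).
Compton recoil electrons deposit locally; there is no bremsstrahlung,
Rayleigh scattering or Doppler broadening.  The first-interaction tally
records only the primary photon's first interaction inside the grid;
secondary tracking (default on, off for the interaction-budget preset)
affects pair-event yields, not that tally.  An infinite-medium mode
disables escape for free-path validation and whole-medium efficiency
arguments.

## Pair production and positron transport

Energy sharing uses the Bethe–Heitler differential shape in the total
energy fraction u (no Coulomb correction; a flat split is available as a
configuration).  Both options are symmetric under e⁺↔e⁻, so the e⁺
kinetic-energy distribution is symmetric about
(E_γ − 2mₑc²)/2 = 0.798 MeV; energy conservation
T₊ + T₋ = E_γ − 2mₑc² holds exactly per event.  Initial lepton
directions are forward-peaked about the photon direction with
characteristic angle mₑc²/E — the reported observables are insensitive
to this choice because multiple scattering decorrelates the direction
within a few steps.

Positrons follow a condensed-history random walk: the CSDA path is
divided into 20 equal-range steps (configurable); each step translates a
uniform random fraction, applies a Gaussian deflection, then finishes
the step (random-hinge scheme).  The deflection width is the Highland
formula θ₀ = (13.6 MeV/βpc)·√(t)·[1 + 0.038 ln(t_full/β²)] with t the
step and t_full the full-path thickness in radiation lengths — the
logarithmic correction is evaluated once at the full thickness because
applying it per sub-step underestimates the accumulated variance.  The
positron annihilates at rest where its range is exhausted (or escapes
the grid).  Annihilation photons are emitted isotropically and exactly
back-to-back by default; a Gaussian acollinearity (0.5° FWHM typical)
is available.  Annihilation-in-flight and energy-loss straggling are not
modelled.

With these conventions the mean displacement |r_a − r_p| for positrons
from 2.617 MeV pair production in water is ≈ 2.45 mm with a 99.9th
percentile of ≈ 6.4 mm.  A Gaussian-only multiple-scattering model
slightly underpopulates both the short-displacement core (no hard
single-scatter folds) and the long straight tail relative to
full-physics codes; this is the main known model limitation and is
visible as a modest (~10%) inflation of annihilation-profile widths.

## Detection and reconstruction

The ring is a cylinder of perfect front-face absorbers: each photon is
projected to its cylinder intersection, accepted with a configurable
efficiency inside the axial extent, blurred in energy (fractional FWHM
at 511 keV) and time (each single gets σ = CRT/(2.355·√2)), and snapped
to the nearest crystal center.  Coincidence sorting opens a prompt
window at each unassigned hit; windows with exactly two in-window,
in-energy-window hits become coincidences, others are discarded.
Randoms are absent by construction because histories are spaced far
apart in absolute time (Poisson arrival times are a configuration away).
Two presets bracket the scanner classes studied: "clinical" (radius
410 mm, 3.2 mm pitch, 214 ps CRT) and "preclinical" (radius 80 mm,
1.12 mm pitch, no TOF).  The acquisition energy/timing windows of the
real scanners are not public; the defaults here are declared, not
inferred.

Reconstruction is list-mode MLEM/OSEM with Siddon ray tracing between
crystal centers; subsets partition events round-robin.  TOF mode
multiplies each LOR's voxel weights by a Gaussian centred at
s = c·Δt/2 from the LOR midpoint with σₓ = c·σ_t/2.  The sensitivity
image is uniform by default (adequate for the point-source and
cold-insert properties tested) or computed from sampled crystal-pair
LORs via `geometric_sensitivity`.  Attenuation factors from the known
μ-map are available but off by default; there are no scatter/randoms
terms and no PSF model.  The Gaussian post-filter uses reflective
boundaries and conserves total intensity.

## Profile analysis conventions

Slice profiles histogram one coordinate of event positions for events
whose two other coordinates lie within a slab of half-thickness 0.5 mm
(one 1 mm tally voxel), in 0.25 mm bins centred on zero; projection mode
aggregates the full volume and is used for the low-statistics 20 cm
material cubes, where it visibly broadens the displayed profile.  The
slab half-thickness matters: the slab's transverse extent adds directly
to the geometric core width of the 1/r² point-source profile, and a
2 mm-thick slab would inflate the fitted production FWHM from ~0.94 mm
to ~1.19 mm.  For sources isotropic about the origin the three axes are
statistically identical, and the water-cube analyses pool them for 3×
variance reduction.

Profiles are peak-normalized and fitted by ordinary least squares with
f(x) = A[1+(x/σ)²]⁻¹ + B·exp(−C|x|), all parameters nonnegative,
initialized from the raw histogram (σ₀ = half the raw half-max width,
B₀ = 0.1, C₀ = 1/(5σ₀)).  The reported FWHM is 2σ of the Lorentzian
component; the numeric half-max width of the total fitted curve is also
reported.  The decomposition into "peak" and "background" is nearly
degenerate when the two scales are comparable — as they are for the
annihilation profile — so single fits at realistic statistics scatter
appreciably (σ ≈ 0.1–0.2 mm at 10⁸ primaries) even though the data are
fine.  The water-cube localization study therefore runs five
independent 10⁸-primary replicates and reports the median fitted FWHM;
weighted-LS, Poisson-ML, tails-first and bootstrap-median variants were
evaluated and were either less stable or biased.  Typical medians are
FWHM_p ≈ 0.94 mm (production) and FWHM_a ≈ 1.6–1.8 mm (annihilation).
"End-points" of sampled distributions are reported as 99.9th
percentiles, which are estimator-stable where a histogram maximum is
not.

## Study presets and problem sizes

* `budget_cube_1` — 1 cm water cube, 10⁶ primaries, secondaries off:
  first-interaction budget with the analytic oracle cross-check.
* `water_cube_10` — 10 cm water cube: positron KE/range statistics and
  x_p/x_a profiles.  The CLI default of 10⁶ primaries is a quick look;
  quantitative FWHMs need the replicated-10⁸ design above, which is
  what the test suite and `scripts/acceptance.py` run (~90 s per 10⁸
  with the vectorized engine).
* `material_cubes_20` — 20 cm cubes of water/adipose/lung/bone:
  production and annihilation efficiency in the central 1 cm³ per
  primary.  The acceptance script uses 10⁷ primaries per material so the
  lung ROI count (the ratio denominator with the fewest events) carries
  ~3% relative noise.  The bone/lung ratio is the quantity most
  sensitive to the assumed lung density (0.26 g/cm³, inflated lung);
  published material definitions vary and the comparison tolerance is
  wide accordingly.
* `six_insert`, `four_rod`, `nu4_small`, `clinical_ppt_imaging` —
  cylinder phantoms (20 cm ⌀ clinical background; 2 mm voxels) with
  uniform sources inside the flagged inserts, optionally carried through
  detection and reconstruction.  Insert layout (60°/90° spacing on a
  5 cm ring, centred axially) is a configurable convention — the
  published figures do not pin exact coordinates.

## What the synthetic studies do not show

The generator emulates idealized physics around a point or
uniform-insert source.  Passing tests establish internal consistency
and agreement with the published *simulation* results at the stated
tolerances; they say nothing about detector microphysics, scatter and
randoms at clinical count rates, real ²¹²Pb solution chemistry or
daughter redistribution in vivo, and the reconstructed-image properties
here (ideal geometry, no normalization) are not NEMA image-quality
measurements.

## Numerical details and degenerate inputs

Seeded `numpy` Generators drive every stochastic step; a run is
bit-reproducible given (grid, config, seed) and chunking does not change
results.  Zero-length LORs backproject to nothing; empty coincidence
lists refuse to reconstruct; voxels with zero sensitivity are excluded
from EM updates (images stay finite and nonnegative); profile fits
require ≥ 10 occupied bins and reject flat input; positron transport at
T₊ = 0 annihilates in place; a vacuum-like grid (μ̂ → 0) escapes every
photon.  Energies outside the 0.05–3 MeV table raise rather than
extrapolate.
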