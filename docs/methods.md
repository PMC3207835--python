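# Methods

`scintcam` models a dual-headed Anger camera imaging the three isotopes
used in liver radioembolization — the pure gamma emitter 99mTc (140.5 keV,
89%), the pure beta emitter 90Y (E_beta,max = 2.28 MeV, imageable only
through its Bremsstrahlung continuum), and the combined beta–gamma emitter
166Ho (betas to 1.85 MeV; gamma lines at 80.6, 1379.4 and 1581.0 keV) —
and computes the standard scintillation-camera quality metrics from
simulated acquisitions.  This note records the models, their assumptions,
the tunable parameters, and what the synthetic data do and do not show.

## Emission models

Gamma lines are taken at their nominal energies and abundances.  Beta
spectra use the allowed-transition shape p·E·(Q−T)²·F(Z,T) with the
nonrelativistic Fermi screening factor F = 2πη/(1−e^(−2πη)), η = αZ/β
(daughter Z: 40 for 90Y→90Zr, 68 for 166Ho→166Er).  Branches are weighted
by their intensities (90Y: 2.28 MeV/99.9%; 166Ho: 1.77 MeV/48.7% and
1.85 MeV/50.0%).  Sampling is inverse-CDF on a 2000-point grid; a
quadrature oracle over the same density is used in the tests.

The Bremsstrahlung continuum is a thick-target model: every beta is
assumed to stop in the surrounding medium (water or PMMA), radiating a
total energy Y(T)·T, where the radiation yield
Y(T) = (1/T)∫₀ᵀ S_rad/(S_col+S_rad) dT′ comes from the embedded
collision-stopping-power table and the rule S_rad/S_col = Z_eff·T/800.
Photon energies follow the Kramers thick-target number spectrum
dN/dk ∝ (T−k)/k.  One dimensionless normalization constant fixes the
absolute photon number against the accepted thick-target yield of 90Y in
water (2.0% of decays produce a photon above 50 keV); the 166Ho yield is
then a prediction of the model (it evaluates to ≈1.3%, against an accepted
≈1.2%).  Only photons above 50 keV are transported: every photopeak window
in use starts at or above 50 keV and energy blur cannot promote softer
photons into a window by tens of keV.  The sub-50-keV continuum therefore
never reaches any tallied quantity; the dead-time constant, the one place
the full photon flux would matter, is a configuration input (below).

## Cross sections

The transport tables cover 10–2600 keV for water, PMMA, lead, NaI, crown
glass, aluminum and air.  Incoherent scattering is analytic Klein–Nishina
per electron; small-angle events are thinned by an incoherent
scattering-function factor S/Z = x²/(q₀²+x²) (x = sin(θ/2)/λ in 1/Å,
q₀ ≈ 0.6 Å⁻¹ for water, scaling with Z_eff^{1/3}), implemented as delta
scattering so that rejected events leave the photon undisturbed.
Photoelectric absorption, coherent scattering (Z^2.9/A scaling, dipole
form-factor angular shape) and pair production are semi-empirical
piecewise power laws anchored at published attenuation values, with K
edges for iodine (33.17 keV) and lead (88.0 keV, Kα fluorescence at
75 keV with an effective yield of 0.75).  Accuracy is a few percent for
the dominant channels in the imaging range; the minor channels are good to
roughly ±10%.  The NaI crystal keeps the free-electron Compton response
(q₀ = 0) so that detection efficiency has the closed form 1−e^{−μt}
asserted in the tests, and coherent scattering is disabled inside the
crystal, where any interaction already counts as detection.

## Transport

Photon-only analog Monte Carlo with per-photon provenance: electrons
deposit locally, pair production deposits E−1022 keV with the annihilation
photons assumed to escape, and iodine K-escape is neglected.  The phantom
is a stack of finite slabs; the camera head is collimator, 1 mm aluminum
entrance window, 3 mm gap, 9.525 mm NaI crystal and a 50 mm crown-glass
backscatter slab, laterally bounded by the 597 mm field of view.

The hexagonal-hole collimator (flat-to-flat hole size, pitch = hole +
septum, per-photon random lattice offset to avoid aliasing) is traced with
Woodcock (delta) tracking against the lead majorant, which is exact for
arbitrary hole shapes without boundary ray tracing.  The septal-contact
flag for undisturbed chords is computed exactly from the distance to the
exit of the entry hexagon: holes are completely separated by lead, so
leaving the entry hole prism before the back plane implies septal contact.

Detected position is the energy-weighted centroid of the crystal deposits,
blurred by the intrinsic resolution; measured energy is the total deposit,
blurred by the energy resolution.  Classification follows the
flag-dominance rule: any detected photon that crossed septal lead is
*penetrated* (whether or not it also scattered); otherwise any scatter
flag or a collimator lead x-ray makes it *scatter*; otherwise *primary*.
Compton interactions inside the crystal are part of the detection cascade
and set no scatter flag — the scatter class contains photons disturbed in
the phantom, the housing, the backscatter compartment or the collimator.

Emission is importance-sampled over direction with two nested cones aimed
at the camera plus an isotropic floor, with exact compensating weights;
the analog limit is retained and the equivalence of the two estimators is
a test.  The biasing accelerates the line-source runs by roughly two
orders of magnitude and is a pure variance device.

## Camera parameters

| parameter | default | why |
|---|---|---|
| intrinsic resolution | 3.5 mm FWHM at 140 keV, ∝ 1/√E | typical 3/8″ NaI camera; not published for this head |
| energy resolution | 9.5% FWHM at 140 keV, ∝ √E | same |
| crystal | 9.525 mm NaI (3/8″) | data sheet |
| collimators | VXGP 1.78/0.152/42 mm, MEGP 2.95/1.143/48 mm, HEGP 3.81/1.727/60 mm | hole / septum / length data sheet |
| full-energy window | 20–2500 keV | low threshold below the usable range |
| planar matrix | 256², 2.332 mm pixels | acquisition setting |

The intrinsic and energy resolutions are calibration knobs held in the
configuration, not constants in code.

## NEMA metrics

The line-spread function sums the central 10 cm of image rows
perpendicular to the source.  Widths follow the NEMA procedure: parabolic
peak through the maximum bin and its neighbours (chosen over maximum-pixel
for noise robustness and recorded in the result metadata), linear
interpolation to the crossing on each side.  A dense-grid brute-force
oracle (1000× upsampling and direct thresholding) agrees to 0.02 mm on
noiseless profiles.

Planar sensitivity is counts/(time·activity) from the Petri-dish geometry
(thin 10 cm disk; 1 cm PMMA above and below for the beta emitters, the
slabs travelling with the dish when the standoff changes).

Count-rate linearity uses the paralyzable model R_obs = R·e^{−Rτ}, fitted
by unweighted least squares (no weighting is prescribed for this
measurement; configurable).  The system curve composes the photopeak
sensitivity with the full-window loss factor,
R_sys(A) = S_peak·A·e^{−S_full·A·τ}, because dead time is driven by every
photon that hits the crystal.  The linear-range limit is evaluated on the
continuous model: A_linmax = −ln 0.98/(S_full·τ) and
R_linmax = 0.98·S_peak·A_linmax.  The camera's τ is not published;
it defaults to 0.2 µs, the largest round value consistent with
S_peak ≤ S_full when S_full·τ is inferred from the published A_linmax
values, and places the intrinsic 2%-loss point near 100 kcps.  R_linmax
itself is independent of the choice of τ.

## SPECT image-quality chain

The torso phantom (9700 ml body of the standard two-half-circles shape,
six coplanar spheres of 10–37 mm on a 57.2 mm ring, cold lung insert of
0.3 relative density) is voxelized at 4.664 mm on a 128³ grid.  The
acquisition is hybrid rather than fully Monte Carlo: 120 parallel-beam
views over 360° are formed as attenuated line integrals (effective
broad-beam μ: 0.12/0.11/0.10 cm⁻¹ for the Tc/Ho/Y windows — stated
defaults, not published values), with each of 16 depth groups convolved by
the distance-dependent system PSF, scaled to the count budget of a
30-minute scan and Poisson-perturbed per pixel.

The PSF is a three-component Gaussian mixture calibrated from transport
runs of the line source in 20 cm PMMA at 120/200/280 mm: the provenance
tags split each run into the primary core, the scatter component and the
septal-penetration component, whose fractions and lateral widths are
measured directly and interpolated in distance.  This split is the reason
the isotopes separate in contrast: the 90Y and 166Ho pedestals carry
50–130 mm wide penetration clouds holding most of the detected counts.

Reconstruction is slice-by-slice FBP with a ramp filter to Nyquist and
linear interpolation (no additional filtering), followed by the Chang
multiplicative correction C = M/Σ_m e^{−∫μ dl} over M = 64 in-plane
directions (64 vs 256 directions differ by under 0.5%, asserted in a
test).  Contrast recovery follows the hot-sphere procedure:
QH = 100·(C_H/C_B − 1)/(R − 1) with C_H from a sphere-diameter ROI on the
central slice and C_B averaged over 55 background ROIs (11 in-plane
positions × 5 slices at 0, ±1, ±2 cm; 55 rather than the 60 of the
current standard, matching the measurement being reproduced).  ROI means
are area-weighted with 4× supersampled pixel coverage.  The dispersion of
the background ROI means doubles as an empirical per-sphere QH
uncertainty, which matters for the 10–13 mm spheres: they span only two
to three voxels, so their single-ROI reading fluctuates by more than five
QH points under ramp-filtered noise.

## Problem sizes and statistics

Desk-scale budgets replace the 3·10⁸-photon runs of a cluster-scale
study: photon-class fractions use 0.9–2.5 million emitted photons with
angular importance sampling (primary-fraction standard errors of about one
percentage point), resolution sweeps 1.5 million per geometry, and PSF
calibrations 0.5–1.2 million per distance.  Statistical uncertainties are
printed beside the Monte Carlo tables; tolerance bands in the tests are
correspondingly wider than counting error alone.

## What the synthetic data do not show

The simulator emulates the measurement geometries, not a clinical scan:
no patient bed or room scatter, no collimator housing or side shielding,
no iodine K-escape or annihilation-photon tracking, cross sections from
semi-empirical fits rather than evaluated libraries, and an aqueous-source
assumption for the Bremsstrahlung target.  The hybrid projector inherits
whatever the PSF calibration cannot see — object-specific scatter of the
torso is represented by the line-in-PMMA scatter environment, and the
depth dependence is linear between three calibration distances.  Passing
tests therefore demonstrate internal consistency of the models and
agreement with the published phantom-scale values at the stated
tolerances, not detector-grade validation on real data.

## Known limitations

* The scatter and penetration pedestals are single Gaussians per class; a
  measured LSF has sharper near-core scatter plus flatter far tails.
* The Chang correction and the forward attenuation use the same effective
  broad-beam μ, which makes the chain self-consistent but sidesteps the
  narrow-beam/broad-beam mismatch a real system shows.
* Dead time is modelled, never transported; the vial geometry enters only
  through the analytic flux argument.
* Coherent scattering in lead uses the same dipole form-factor shape as
  the light materials; its cross section there is the least certain number
  in the tables.
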