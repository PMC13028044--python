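# Methods

This note documents the models behind `atcmdose`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Materials and spectra

Photon interaction data are a compact compilation of standard tabulated
mass attenuation and mass energy-absorption coefficients for air, lung,
adipose, soft tissue, water, cortical bone, aluminium and PMMA on a
ten-point grid spanning 10–150 keV, interpolated log–log (a few-percent
accurate for these smooth cross sections). The incoherent column is the
free-electron Klein–Nishina value scaled by Z/A (binding neglected, capped
at the tabulated total minus photoelectric where the free-electron value
would exceed it); coherent (Rayleigh) scattering is the tabulated
remainder and is excluded from transport — a <5 % effect on absorbed dose
at CT energies, and a large simplification of the kernel.

The tube spectrum is filtered Kramers bremsstrahlung, fluence ∝
(kVp − E)/E on 1 keV bins, hardened by aluminium filtration;
characteristic lines, heel effect and off-focal radiation are omitted.
Beam quality is summarised by the aluminium half-value layer with
air-kerma weighting (what an ionisation chamber measures), solved by
bisection to |K/K₀ − ½| < 10⁻⁶; `tune_filtration_to_hvl` inverts the
strictly monotone HVL–filtration relation by bisection, so a spectrum can
be anchored to a measured HVL — the same information content a
measurement-driven spectrum model carries. With these defaults the 120 kVp
/ 3.5 mm Al beam has HVL ≈ 3.8 mm Al, on the soft side of modern CT beams
because the continuum lacks characteristic lines; all comparisons in the
pipeline are internally consistent with the same spectra.

The bowtie filter is a parabolic aluminium-equivalent thickness profile
t(γ) = t_max (γ/γ_max)², t_max = 15 mm by default: zero on the central
ray, maximal at the fan edge, applied to photons as a survival weight at
emission (equivalent in expectation for primaries; filter scatter is out
of scope). Vendor bowtie dimensions are proprietary, so these are
archetype placeholders, not product data.

## Scanner archetypes

Vendor ATCM firmware is proprietary; the package therefore works with
mechanism-level archetypes rather than product emulations:

* **prospective_magnification** — tube current fixed before the scan from
  localiser apparent widths; inherits geometric magnification errors.
* **online_lag** — prospective prediction plus real-time feedback: the
  first half rotation runs without feedback, after which the current at
  gantry angle θ is recomputed from the attenuation observed at θ − π
  (half a rotation, i.e. half a table increment, earlier).
* **size_compensated** — patient size estimated from localiser
  *attenuation* (4/π × mean water-equivalent path, exact for a circular
  section) instead of apparent width, which cancels magnification; the
  `lateral_failure` variant drives the current to the tube ceiling once
  the lateral shift reaches 20 mm, reproducing the observed complete
  breakdown of some systems under lateral off-centring.

The modulation rule is mA = clamp(mA_ref · exp(s·μ_eff·(WED − WED_ref)),
mA limits) with defaults s = 0.5, μ_eff = 0.02 mm⁻¹, mA_ref = 120,
clamp 10–800 mA. s = 1 would be full constant-noise compensation
(≈ doubling mA per ~35 mm of extra water); vendors damp this, and 0.5 is
mid-range. Dual orthogonal localisers combine as WED = √(w_frontal ·
w_lateral) (the equal-area ellipse rule). Angular (xy) modulation is off
by default; the studied effects are carried by z-modulation.

**Per-scout-mode anchoring.** Width sizing (circular assumption) and
elliptical or attenuation sizing disagree systematically by ~15 % on an
elliptical torso. Real systems do not change their noise target with the
scout configuration, so the experiment runner anchors WED_ref per
localiser mode on the centred reference phantom: any scout configuration
of the centred reference yields mA_ref, and only deviations from that
state modulate the current. The online feedback rule is likewise anchored
to the centred phantom's mean central-ray water-equivalent path.

## Localiser model

The localiser is projected slice-by-slice with a 2D fan per z row (no
cone divergence along z — second order for per-z size estimates), ray
marching at a single effective energy (the kerma-weighted mean of the
localiser spectrum) with step ≤ half the minimum voxel spacing, onto a
1 mm-pitch virtual detector at twice the source–isocentre distance. Rays
with water-equivalent path > 5 mm count as body (robust to skin-voxel
aliasing). Detector edge coordinates are rescaled by u → SID·sin(atan(u/SID))
before taking the silhouette extent: this inverts the tangent-ray geometry
so an axis-centred cylinder reconstructs to its true diameter and an
offset one scales by SID/(SID − d) to within one detector pixel — the
package's model of how scanners calibrate localiser width at isocentre
scale. Frontal widths remain invariant to lateral shifts (and lateral
widths to vertical shifts) to second order, ≈ 0.7 % at a 60 mm shift.

## NRMSE profile translation

Deviations measured on the reference phantom are transferred onto each
model's own reference profile. The phantom's reference and deviating
profiles are compared sample-by-sample; indices are partitioned into
maximal runs where the deviating current is consistently higher, lower or
equal (within 1 % relative — quantised mA values make exact equality
brittle). Each non-equal run P receives a signed factor
f_P = 1 + sign·NRMSE_P with NRMSE_P = √(mean((dev−ref)/ref)²) over the
run; equal runs keep f = 1, so identical profiles leave the patient
profile untouched. The relative (per-sample-normalised) RMS is used
because it makes a uniformly scaled deviation dev = c·ref translate to
exactly c× the patient profile for any reference shape; a run-mean
normalisation would not. Run extents map onto the patient scan range by
fractional position (midpoint convention), and factors are applied
multiplicatively (dimensional consistency).

## Monte Carlo dose engine

Photon transport uses delta (Woodcock) tracking against a per-energy
global majorant on the voxel grid: unbiased in heterogeneous media with no
per-voxel boundary crossings. Interactions are photoelectric absorption
and Klein–Nishina incoherent scattering (Kahn's sampling); energy
transferred to electrons is deposited locally (kerma approximation —
standard for CT organ dosimetry at these energies and 5 mm voxels), and
photons are terminated below 10 keV with residual energy deposited
locally. Energies live on 1 keV bins from 10 to 150 keV.

The helical source path has table increment = collimation × pitch, with
z-overscan of half a collimation beyond each end of the scan range
(deliberately simplistic; full overscan modelling is out of scope).
Emission times are importance-sampled proportional to the tube-current
profile, the fan angle is uniform within the fan, the cone offset uniform
within the collimation, and the bowtie enters as an emission weight. The
gantry start angle is randomised per photon: scanners do not synchronise
the start phase, and with only ~4 rotations per chest scan a fixed phase
makes small edge organs' dose depend on the arbitrary angle at which the
tube passes their z (±20 % for the thyroid) — per-photon randomisation is
the ensemble average over scans. The fixed-beam oracle mode keeps a fixed
angle instead.

Absolute dose is anchored by free-in-air air kerma at the isocentre: the
configured nominal output (mGy per 100 mAs, per kVp) divided by the
simulated kerma per photon (perpendicular-disc fluence estimator, 10 mm
radius) gives photons-per-mAs; the tally is scaled by that factor times
the scan's total mAs. Dose is therefore exactly linear in a global mA
scale at fixed seed. Kerma per photon is *not* monotone in kVp with these
soft spectra — E·μ_en(air) has a minimum near 60–70 keV — which is why the
tests validate the kerma estimator against a deterministic quadrature
rather than a monotonicity claim; per-mAs output ordering across kVp is a
calibration input, not a simulation output.

Default photon counts are desk-scale choices: 2×10⁵ per scan in grid runs
(per-organ MC standard errors ≲ 1–2 % for the lungs, ~5–10 % for the
thyroid), 10⁶ for the primary-only Beer–Lambert oracle, 4×10⁵ per kerma
calibration. A production-scale engine would use orders of magnitude more;
every count is a parameter.

## Synthetic phantoms

Anatomy is parametric: stacked elliptical torso cross-sections (half-axes
per BMI class from 115×80 mm to 165×115 mm, +3 % for male models, ±4 %
seeded jitter), a subcutaneous adipose shell, two lung ellipsoids (0.26
g/cm³), heart, liver crossing the caudal scan edge, thyroid above the
cranial edge, a bone spine, and breasts (adipose) for female models; organ
masks are made pairwise disjoint by priority. The grid is 96×72×72 at
5 mm isotropic ((z, y, x); z+ cranial, y+ anterior, x+ patient right). The
fixed reference phantom (adult male, normal BMI, fixed seed) plays the
role of the physical phantom from which deviation profiles are measured.

What this emulates: realistic z-varying attenuation (lungs vs
liver/shoulders) that drives modulation, organ positions relative to the
scan range, BMI-scaled body size, the sex split for breast dose. What it
does not: image-derived anatomy, arms, respiratory motion, inter-organ
heterogeneity, realistic bone marrow — so passing tests demonstrate the
*mechanisms* (magnification chains, compensation, lag effects), not
patient-accurate absolute organ doses.

## Experiments and statistics

The deviation grid mirrors the study design: reference = PA localiser,
caudocranial scan, centred; families = localiser angle (AP, LAT, PA+LAT,
AP+LAT), scan direction (craniocaudal with single PA or dual PA+LAT), and
vertical/lateral off-centring (±2/4/6 cm), each off-centre setup with
single and dual localisers, offsets applied identically to the localiser
and the rotation axis (the patient does not move between scout and scan).
Per-(model, setup) seeds derive from the master seed by hashing, so single
setups can be re-run without perturbing others and full runs are
byte-reproducible.

Organ dose is the voxel mean over the mask (masks are single-material, so
mass weighting would change nothing). Relative differences are computed
per model and then averaged (mean ± SD across models). The statistics are
classical: paired t for the direction family; one-way repeated-measures
ANOVA (subject blocking) with Dunnett many-to-one contrasts on the pooled
within-subject error for the angle and off-centring families, the
adjusted p obtained from the correlation-½ multivariate-t null by seeded
Monte Carlo (2×10⁵ draws; verified in tests against a 10⁶-draw data-level
simulation); Bland–Altman bias ± 1.96·SD limits of agreement for
single-vs-dual pairings (the 1.96 convention, not a t-multiplier).
Normality is not re-tested as a gate; a Shapiro–Wilk diagnostic is
available for transparency.

## Known limitations

No electron transport (kerma approximation), no Rayleigh scattering, no
characteristic X-ray lines, no scatter in the localiser, no localiser-dose
accounting, no image formation or noise evaluation, simplistic overscan,
archetype (not vendor) scanner parameters, and parametric (not
image-derived) anatomy. The pipeline reproduces mechanism-level patterns —
monotone dose increase with downward offset under width-based ATCM, √M
dual-localiser mitigation, lateral-failure saturation, the direction
dependence of online modulation near the thyroid — not the numeric
percentages of any specific commercial scanner.
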