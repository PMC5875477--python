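# Methods

## Scope and model

`cbctdose` computes absorbed dose from kilovoltage cone-beam CT acquisitions
by analog Monte Carlo photon transport on voxel grids. The physics is
deliberately restricted to what matters between 10 and 150 keV in low-Z
media:

- **Photoelectric absorption** deposits the full photon energy in the
  interaction voxel (fluorescence escape is neglected; for Z ≤ 20 the K yield
  and K energies are small).
- **Incoherent (Compton) scattering** samples the scattered-photon fraction
  ε = E′/E from the free-electron Klein–Nishina distribution,
  p(ε) ∝ ε + 1/ε − sin²θ(ε) on [1/(1+2α), 1], by rejection against the bound
  ε_min + 1/ε_min. The electron energy E − E′ is deposited locally. Binding
  effects and Doppler broadening are ignored (a few-percent effect at these
  energies, largest below ~20 keV).
- **Coherent (Rayleigh) scattering** deflects without deposition, with the
  Thomson angular law (1 + cos²θ). Real coherent scattering is more forward
  peaked (atomic form factor); since coherent events are only a few percent
  of interactions this approximation is accepted and the process can be
  toggled off entirely (`include_coherent`).
- **No electron transport.** Collision kerma is identified with absorbed
  dose; secondary-electron ranges at ≤125 keV are sub-millimetre, below the
  voxel sizes used. Photons falling below the **10 keV cutoff** deposit
  locally and terminate.

Tracking uses **Woodcock (delta) tracking**: free paths are drawn against a
grid-wide, energy-dependent majorant attenuation coefficient; at each
tentative collision the real-interaction probability is μ_local/μ_majorant,
and the process is drawn proportionally to the partial attenuation
coefficients. This is unbiased for arbitrary voxel heterogeneity and was
validated against the Beer–Lambert law for unscattered transmission.

Two tallies are filled in one pass:

- the **analog energy-deposition map** (used for organ doses and the energy
  ledger), and
- a **collision-kerma estimator** scored at *every* Woodcock vertex, real or
  fictitious: each vertex in a voxel contributes w·E·(μ_en/ρ)_local /
  (μ_majorant·V). This estimator has far lower variance in low-density
  scoring volumes and is the default for the air-filled CTDI holes, where
  analog deposition events are rare.

Every run verifies an exact energy ledger — emitted = deposited + escaped to
1 part in 10⁶ — and aborts otherwise.

## Source and beam

The spectrum model is a Kramers bremsstrahlung continuum, fluence(E) ∝
(E_max − E)/E, attenuated by exp(−μ_Al(E)·t), plus tungsten characteristic
lines Kα₂/Kα₁/Kβ₁/Kβ₂ at 57.98/59.32/67.24/69.07 keV carrying 5 % of the
filtered fluence by default. Bins are 1 keV with bin-center sampling.
Tabulated spectra can be substituted via a two-column CSV
(`energy_keV,relative_fluence`).

Default filtration is 2.5 mm Al inherent plus 3.0 mm Al added. The total of
5.5 mm Al-equivalent was chosen so the generated 125 kVp beam's half-value
layer (5.47 mm Al, computed by the package) matches the published beam
quality of the on-board kV imager class being modeled; a bare Kramers
continuum is otherwise unrealistically soft because it omits anode
self-filtration.

Continuous 360° rotation is modeled by drawing an independent uniform gantry
angle per photon — the limit of a many-projection acquisition and the
cheapest unbiased choice. Directions are uniform over the rectangular
fan/cone acceptance covering a 40 × 30 cm detector at 150 cm; the half-fan
mode offsets the acceptance laterally by 14.8 cm at the detector plane. The
bowtie filter enters as a multiplicative photon weight
exp(−μ_Al(E)·t(φ)/10), keeping the transport analog.

**Bowtie profiles.** Real profiles are proprietary, so parametric
compensators are used: thickness t(φ) is chosen so that bowtie plus the
chord of a water cylinder is constant across the fan, clipped to
[0.2, 30] mm, evaluated at a 60 keV design energy. The half-fan bowtie
compensates a 30 cm water cylinder (asymmetric over the offset fan). The
full-fan bowtie compensates the cylinder filling the imaged field of view
(radius = SAD·tan φ_max ≈ 13.3 cm): designing it on the 16 cm head phantom
itself over-flattens and inverts the head dose profile, whereas the FOV
design reproduces the observed near-flat head distribution
(periphery/center ≈ 1.0). Custom profiles can be loaded from CSV
(`fan_angle_deg,thickness_mm`).

## Interaction data

Elemental photon cross sections (H, C, N, O, Na, Mg, Al, P, S, Cl, Ar, K,
Ca; 10–150 keV, 10 grid points, log-log interpolated) are embedded as frozen
tables. Totals for H, C, N, O and Al follow standard published
compilations; the minor tissue/bone elements were reconstructed from a
photoelectric Z–E scaling anchored on Al/P/Ca plus the exact Klein–Nishina
incoherent term and a calibrated coherent fit, and checked against the ICRP
cortical-bone total. The split into processes is total-preserving:
incoherent is the free-electron KN value capped by the total, coherent a
Z²/E^1.45 fit, photoelectric the remainder. Water and PMMA totals reproduce
reference values to better than 0.5 % (2 % is the design target); the
per-process split is approximate below ~20 keV where the incoherent
scattering function is neglected. Mass energy-absorption coefficients for
air and water are embedded directly from trusted compilations (they drive
the HVL integral and the air-hole kerma estimator); elemental μ_en values
use the energy-transfer approximation pe + incoherent·f_KN(E).

Materials are element mixtures with bundled definitions (air, water, PMMA
1.19 g/cm³, lung 0.26, adipose 0.95, soft tissue 1.06, cortical bone 1.92,
vertebral spongiosa 1.18, aluminum). The CT-number conversion builds a
piecewise-linear HU→density map over configurable anchors (defaults: air
−1000 HU to cortical bone +1300 HU) quantized into bins no wider than the
density tolerance (default 0.05 g/cm³); bins take the density of their lower
edge so anchors map to themselves, and breakpoint ties go to the higher
segment.

## Phantoms

**CTDI phantoms** are PMMA cylinders, 15 cm high, 16 cm (head) or 32 cm
(body) diameter, voxelized at 2 mm with air-filled holes of 1.31 cm diameter
(standard chamber bore) at the center and at 7 cm (head) / 15 cm (body)
radial offset, 90° apart, hole A at gantry angle 0°. Scoring uses the full
15 cm air column by default; a centered chamber length (e.g. 100 mm) is
configurable. The grid is centered on the isocenter with even in-plane
dimensions so the voxelization is exactly symmetric under 90° rotation.

**Voxel phantoms** are labeled volumes with per-label materials and a
separate organ-label volume, read and written in a minimal interfile-style
dialect (ASCII key-value header + raw little/big-endian label volume,
x-fastest). Dose volumes can be exported as MetaImage (.mhd/.raw).

**Synthetic anatomy.** The four site phantoms (head-and-neck, chest,
abdomen, pelvis) reproduce the acquisition grid of the reference anatomy —
512×512 in-plane at 0.84×0.84 mm², 2.5 mm slices, with 120/95/160/65 slices
per site — and carry the site's organ inventory (e.g. eyeball/brain/cord for
the head, paired lungs/heart/cord for the chest, pelvic organs by sex). They
are built from an elliptical soft-tissue trunk with a 3 mm skin shell, a
posterior vertebral column containing the cord, and ellipsoidal/tubular
organs at canonical positions with small seeded jitter (regenerated with
shrinking jitter on overlap, mutually disjoint by construction). The default
downsample factor 4 (128×128 in-plane, 3.36 mm pixels) keeps an organ-dose
run under a minute; factor 1 reproduces the full grid. These phantoms emulate
the *structure* of real labeled anatomy — grid, organ set, ordinal placement,
plausible masses — but not subject-level shapes, organ-specific densities
(all non-lung organs are 1.06 g/cm³ soft tissue) or motion. Tests passing on
them demonstrate pipeline correctness and physical consistency (positivity,
mAs linearity, dose ordering with depth), not agreement with any specific
human's organ doses.

## Calibration and reporting

Raw tallies are mean doses per history in keV/g. Absolute doses follow

D[cGy] = tally × Ω_beam × mAs × F,

where Ω_beam is the fan/cone angular acceptance (so differently collimated
scans share one tube-output normalization) and mAs = mA × ms × pulses (the
pulse count per rotation is not part of the published protocols; it defaults
to 1 and cancels between modes). The factor F is fixed by a single-point
anchor: the simulated head-phantom standard-mode CTDIw is set to the
published 8.90 cGy. Body-phantom and organ doses are then genuine
predictions. Linearity in mA·ms is exact by construction, so the low-dose
protocol (40 mA, 10 ms) delivers exactly 20 % of the standard protocol
(80 mA, 25 ms) for identical geometry and seed.

Point and organ doses are mass-weighted means over their scoring volumes.
Uncertainties come from batch statistics (default 10 independent batches per
run, seeded via spawned substreams of the run seed; bit-reproducible for a
fixed seed and batch/chunk configuration). For scoring regions registered at
run time the batch tallies are exact; mask-based queries estimate σ from
per-voxel squared accumulators, which neglects inter-voxel covariance.

## Problem sizes and numerical choices

CTDI runs use 2×10⁶ histories in 10 batches (seconds per run; peripheral-hole
kerma statistics ≈ 1 %, central-hole ≈ 2–3 % in the body phantom). Organ runs
use 3–5×10⁵ histories at downsample 4. Cross sections are pre-interpolated
onto a 1 keV grid; partial coefficients are rescaled to sum exactly to the
log-log-interpolated total so Woodcock attenuation matches the analytic
attenuation call identically. Photon energies index the grid by nearest bin.
Degenerate inputs fail loudly: empty phantoms, zero majorants, empty scoring
masks, non-monotone spectra and inconsistent header/raw sizes all raise
typed errors.

## Known limitations

- The bowtie profiles and pulse counts of the real device are unpublished;
  the parametric compensators reproduce the per-phantom dose *distributions*
  (flat head profile; body periphery/center ≈ 1.6) but the cross-phantom
  absolute transfer from a head-anchored calibration underpredicts the body
  CTDIw by roughly a third relative to published values, which is consistent
  with mode-dependent acquisition details the model cannot know. Supplying
  measured bowtie profiles via CSV is the intended correction path.
- Free-electron Compton and Thomson-shaped Rayleigh are few-percent
  approximations, worst below 20 keV where little filtered fluence remains.
- No couch, no detector backscatter, no image formation.
- The synthetic anatomy is structural, not anatomical (above).
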