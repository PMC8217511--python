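# Methods

## Rigid-body assembly model

Each SAS-6 homodimer is a rigid unit carrying a frame at its head-to-head
vertex and a straight "spoke" along the coiled-coil direction. The oligomer
is the orbit of a seed unit under powers of a single inter-unit rigid motion
(the *step*). All public angles are degrees, lengths nanometres; frames are
right-handed and helix handedness is the sign of the rise along the
canonically oriented screw axis.

**Screw decomposition.** A proper rigid motion (R, t) is decomposed into
rotation angle θ ∈ [0, 180] (from the trace of R), unit axis **a** (from the
skew part; at θ ≈ 180° the axis comes from the symmetric eigenproblem, its
sign chosen so the rise is non-negative, with a warning), rise *d* = **a**·t,
and an axis point solving (I − R)c = t⊥, reported perpendicular to the axis
so it is unique. Pure translations are the θ = 0 special case with the axis
along t. Reconstruction/decomposition round-trips to < 1e-6.

**Step construction.** `interface_step(rotation, rise, chord)` places the
screw axis along z at the offset that makes consecutive unit origins
`chord` apart: the in-plane component is 2ρ·sin(θ/2) with ρ the axis
offset, so ρ = √(chord² − rise²) / (2 sin(θ/2)). The default chord is
7.87 nm, back-computed so that a ninefold ring has a 23 nm vertex-circle
diameter; it is a configurable calibration constant, and the same value
parameterises the EM class centres so one constant controls both pipelines.
Whether the 23 nm in the source imaging is the head-vertex, spoke-hub or
outer diameter is not fully determined; the head-vertex reading is used
throughout and flagged here rather than silently assumed.

**Classification.** A step is a closed ring of *n* units when |rise| is
below the closure gap tolerance and applying the step *n* = round(360/θ)
times returns the seed frame within 0.5 nm and 5° (both below the pixel
scale of the imaging the model is compared against); *n* is searched in
[3, 48] with ties broken toward the smaller closure gap. Multi-wrap
closures (nθ ≡ 0 mod 360 with nθ > 360) are *not* rings — the units would
pass through each other — and classify as arcs. A step with appreciable
rise is a helix (pitch = rise · 360/θ, radius from the seed's offset to the
axis). A zero-rotation step with non-zero translation is a straight
filament, reported as an open arc of zero arc angle; zero rotation *and*
zero translation is a degenerate-step error. A finite assembly is labelled
a closed ring only when its unit count equals the closure order; shorter
or longer propagations of the same step are open arcs.

**Landing spokes.** For a helix lying with its axis in the surface plane,
spokes pointing sideways (azimuth strictly within the visible sector,
default 30°, of either lateral direction) are taken as observable; the
pattern of their axial positions gives a maximal same-side spacing of one
pitch (26 nm for the fourfold helix) and 13 nm between opposite sides. The
spoke length itself (default 10 nm) is a drawing parameter — only the ring
and pitch scales are constrained by data.

## Structure analysis

PDB-format I/O goes through gemmi; the first model is used, HETATMs are
retained and tagged, and for alternate locations the highest-occupancy
conformer wins (ties → 'A'). Superposition pairs atoms on
(chain-role, residue number, atom name), Cα-only by default — the common
convention when an "overall RMSD" is quoted without granularity — and
minimises RMSD by SVD (Kabsch) with the determinant correction. The
inter-unit transform of two copies in one structure is the Kabsch motion
screw-decomposed; its rise is in ångström (the PDB unit) and callers
convert to nm where needed.

Domain tilts are angles between dominant principal axes (largest right
singular vector of centred Cα coordinates) after superposing both
structures on a shared axis selection, reported in [0, 90]; a domain whose
axis ratio is < 1.2 is flagged as too isotropic for a well-defined axis.
The reference structures for the published ~7° and ~45° tilts are external
to this package; the operation accepts any user-supplied reference.

Contacts are residue pairs with any heavy-atom distance ≤ 4.0 Å (a
conventional cutoff; the source describes its interactions qualitatively).
Buried interface area uses Shrake–Rupley sampling with 960 Fibonacci points
per atom, probe 1.4 Å, and fixed radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å
(hydrogens ignored); the headline number is the per-side convention
(ΔSASA/2, PISA-style — the magnitudes of published interface areas for a
~10 kDa binder match this convention), with the total ΔSASA also returned.
The implementation is validated against the 4π(r + probe)² closed form for
a single sphere and cross-checked against an independent implementation
(biotite) in the tests.

## AFM pipeline

The synthetic renderer draws an assembly as Gaussian-cross-section ridges
(σ 1 nm, crest 4.5 nm — the height scale of SAS-6 on mica): rings and arcs
as the circular hub through the unit-vertex circle plus radial spokes,
helices as their landing projection (an axial backbone with lateral spokes
at the landing-pattern positions). The hub is drawn as a circle rather
than the vertex polygon: the head domains are extended bodies and the
imaged crest follows the hub circle, whereas a chord-polygon cartoon would
bias every fitted diameter low by ~4% as an artefact of the cartoon, not of
the pipeline under test. Spokes are drawn at 70% of the hub crest — the
coiled-coil is a thinner feature than the globular heads — and overlapping
ridges combine by maximum, not sum. Tip broadening is a Gaussian blur of
configurable σ (default 2 nm) with the crest height preserved. The default
pixel size is 1200 nm / 1024 px ≈ 1.17 nm. Noise is i.i.d. Gaussian,
seeded.

Detection thresholds the map (default 2 nm), labels connected components,
extracts per-angular-bin crest points, and accepts a component as a ring
when a Taubin circle fit has small residual, the fitted radius is in range,
and the crest covers ≥ 70% of the angular range — arcs and helical
(linear) assemblies fail this filter. The Taubin fit is preferred over the
Kåsa fit for its much smaller radius bias on partial arcs. An accepted
candidate is refined by relocating the crest along 40 radial rays on a
lightly smoothed map; because spokes project outward, the hub crest is the
*innermost* strong peak along each ray, and rays whose crest is dragged off
the circle (e.g. along a spoke) are discarded by a MAD filter before the
refit.

The height analysis follows the measurement procedure exactly: 40 radial
profiles at even 9° spacing (the only symmetric choice; the spacing is not
otherwise specified) over radius ± 8 nm with bilinear interpolation; per
profile, height = maximum − baseline with the baseline taken as the
profile's own minimum (the procedure's wording; a global background plane
option exists but is off by default, and per-ray baselining makes the
analysis exactly invariant to a constant offset of the whole map); per
ring, the *height difference* is max − min of the 40 heights. Line scans
subtract the scan minimum ("relative height") and report consecutive
spacings of peaks above a prominence threshold.

## EM pipeline

Synthetic top-view particles are centred annuli with Gaussian radial
cross-section at the model diameter chord/sin(π/n), optional n-fold spokes,
and seeded Gaussian noise with SD = crest/SNR; default pixel size 0.349 nm
(the coarser of the two detector calibrations in the source data, i.e. the
harder case). The centre profile is either a literal single horizontal
scan (the assay's procedure over software-aligned particles) or, by
default, a rotational average over 36 orientations, which substitutes for
the external alignment software this package does not reproduce. Particles
whose intensity centroid is off by > 10% of the frame are re-centred first.

The diameter is the distance between the two outermost peaks above a
prominence threshold (prominence is measured on the range-normalised
profile, so the diameter is invariant to global gain), with parabolic
sub-pixel refinement; profiles with fewer than two peaks are flagged
unmeasurable and counted, never silently dropped. Classification assigns
the n ∈ [7, 11] minimising |D − chord/sin(π/n)|, unassigned beyond a 1.2 nm
window (half the smallest inter-class gap; the binning rule of the source
analysis is not stated, so the window is a documented choice).
Distributions report per-replicate class fractions summing to 1 (including
unassigned and unmeasurable) and mean ± SD across replicates, matching the
"mean ± SD over independent experiments" convention; a single replicate
reports SD 0.

## ITC model

Fraction bound is the exact quadratic solution
complex = ((P + L + K) − √((P + L + K)² − 4PL)) / 2, fraction = complex/P,
with concentrations in µM and K_D in nM; it reduces to L/(L + K) as P → 0
and never exceeds that limit. The titration simulator uses the standard
perfusion (overflow) cell: each injection of dV first scales all cell
concentrations by (1 − dV/V₀), then delivers dV·L_syr/V₀ of titrant; the
heat of injection i is V₀·ΔH·(C_i − C_{i−1}(1 − dV/V₀)). Summed heats
therefore equal ΔH times the total complex *formed*, counting the fraction
expelled by displacement — the conservation check in the tests does that
accounting independently. Default schedule: 20 × 2 µL into a 200 µL cell,
10 µM in the cell, 100 µM in the syringe (the tenfold excess used for 1:1
complexes).

Fitting is trust-region least squares over (log₁₀ K_D, ΔH, n, heat offset),
with the first injection excluded by default (standard practice: its
delivered volume is unreliable) and a deterministic initialisation (n = 1,
ΔH from the first fitted heat, K_D from a c ≈ 10 heuristic). A Wiseman
c-value n·P/K_D outside [0.5, 1000] triggers a warning that K_D is poorly
constrained. Noiseless round trips recover parameters to ~1e-4 relative;
at 2% heat noise the median K_D over 50 seeded runs is within a few percent
of truth.

## Synthetic data and seeds

All randomness flows through `numpy.random.default_rng` seeded from a
single global seed expanded to per-fixture streams via
`SeedSequence(seed, index)`; fixtures regenerate byte-identically and every
manifest records the generator parameters, which suffice to score the
downstream pipelines without reference to generator internals. Generator
defaults are the study conditions: 80/20 nine/eightfold mixtures with 2612
particles across 3 replicates at SNR 3; 50 AFM rings with diameters
18–28 nm and 0.3 nm height noise; titrations at K_D 566/134/137 nM with 2%
heat noise. What the generators do *not* emulate: real tip geometry and
scanner artefacts, CTF and ice background, out-of-register ring stacking,
baseline drift in power traces. Passing tests therefore demonstrate the
correctness and calibration of the measurement procedures under controlled
conditions, not robustness to every instrument artefact.

## Problem sizes and limitations

The default test and reproduction runs use the full stated problem sizes
(2612 particles, 50 titrations, 50 rings); each completes in seconds on one
CPU. The accession-tagged structural comparisons (inter-homodimer twist,
binding-mode RMSD, interface areas of the deposited co-crystals) require
the deposited coordinate files, which are not bundled; the report and test
suite evaluate them when a PDB directory is supplied and mark them skipped
otherwise. Units are rigid — no flexibility, energetics or kinetics — and
the EM pipeline analyses only the annulus diameter, not stacking register
or spoke counts.
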